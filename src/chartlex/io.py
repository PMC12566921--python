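"""Readers and writers for the pipeline's plain-text interchange formats.

Patients and truth travel as CSV, notes as JSONL, the lexicon as YAML (see
:mod:`chartlex.lexicon`).  Readers validate schemas and report offending
line numbers; writers round-trip exactly through the readers.
"""
from __future__ import annotations

import csv
import json
from os import PathLike
from pathlib import Path
from typing import Dict, List, Sequence, Union

from .errors import InputError, IntegrityError
from .types import AnnotationRecord, ClinicalNote, OutcomeRecord, Patient, SentenceTruth

PathArg = Union[str, PathLike]

_PATIENT_FIELDS = ["patient_id", "age_group", "race", "insurance", "outcome_group"]
_NOTE_KEYS = ["note_id", "patient_id", "encounter_id", "note_type", "timestamp", "text"]


def write_patients(patients: Sequence[Patient], path: PathArg) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_PATIENT_FIELDS)
        for p in patients:
            w.writerow([p.patient_id, p.age_group, p.race, p.insurance, p.outcome_group])


def read_patients(path: PathArg) -> List[Patient]:
    patients, seen = [], set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_PATIENT_FIELDS) - set(reader.fieldnames):
            raise InputError(f"{path}: expected header {_PATIENT_FIELDS}")
        for lineno, row in enumerate(reader, start=2):
            try:
                p = Patient(**{k: row[k] for k in _PATIENT_FIELDS})
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            if p.patient_id in seen:
                raise IntegrityError(f"{path}:{lineno}: duplicate patient_id {p.patient_id}")
            seen.add(p.patient_id)
            patients.append(p)
    return patients


def write_notes(notes: Sequence[ClinicalNote], path: PathArg) -> None:
    with open(path, "w") as fh:
        for n in notes:
            fh.write(json.dumps({k: getattr(n, k) for k in _NOTE_KEYS}) + "\n")


def read_notes(path: PathArg) -> List[ClinicalNote]:
    notes, seen = [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                payload = json.loads(line)
            except json.JSONDecodeError as exc:
                raise InputError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            missing = set(_NOTE_KEYS) - set(payload)
            if missing:
                raise InputError(f"{path}:{lineno}: missing keys {sorted(missing)}")
            try:
                note = ClinicalNote(**{k: payload[k] for k in _NOTE_KEYS})
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            if note.note_id in seen:
                raise IntegrityError(f"{path}:{lineno}: duplicate note_id {note.note_id}")
            seen.add(note.note_id)
            notes.append(note)
    return notes


def write_outcomes(records: Sequence[OutcomeRecord], path: PathArg) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "smm_codes", "readmission_day", "birthweight_g",
                    "gestation_weeks", "instrument_assisted", "nicu_admit"])
        for r in records:
            w.writerow([r.patient_id, ";".join(r.smm_codes),
                        "" if r.readmission_day is None else r.readmission_day,
                        r.birthweight_g, r.gestation_weeks,
                        int(r.instrument_assisted), int(r.nicu_admit)])


def read_outcomes(path: PathArg) -> List[OutcomeRecord]:
    records = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                records.append(OutcomeRecord(
                    patient_id=row["patient_id"],
                    smm_codes=[c for c in row["smm_codes"].split(";") if c],
                    readmission_day=(None if row["readmission_day"] == ""
                                     else int(row["readmission_day"])),
                    birthweight_g=int(row["birthweight_g"]),
                    gestation_weeks=float(row["gestation_weeks"]),
                    instrument_assisted=bool(int(row["instrument_assisted"])),
                    nicu_admit=bool(int(row["nicu_admit"])),
                ))
            except (KeyError, ValueError, InputError) as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_truth(truths: Sequence[SentenceTruth], path: PathArg) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sentence_id", "note_id", "patient_id", "label", "keyword"])
        for t in truths:
            w.writerow([t.sentence_id, t.note_id, t.patient_id, t.label, t.keyword or ""])


def read_truth(path: PathArg) -> List[SentenceTruth]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SentenceTruth(
                sentence_id=row["sentence_id"], note_id=row["note_id"],
                patient_id=row["patient_id"], label=row["label"],
                keyword=row["keyword"] or None))
    return out


def write_annotations(records: Sequence[AnnotationRecord], path: PathArg) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sentence_id", "label_a", "label_b", "final_label", "excluded"])
        for r in records:
            w.writerow([r.sentence_id, r.label_a or "", r.label_b or "",
                        r.final_label or "", int(r.excluded_from_modeling)])


def read_annotations(path: PathArg) -> List[AnnotationRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(AnnotationRecord(
                sentence_id=row["sentence_id"],
                label_a=row["label_a"] or None, label_b=row["label_b"] or None,
                final_label=row["final_label"] or None,
                excluded_from_modeling=bool(int(row["excluded"] or 0))))
    return out


def write_predictions(rows: Sequence[Dict], path: PathArg) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sentence_id", "score", "label"])
        for r in rows:
            w.writerow([r["sentence_id"], f"{r['score']:.6f}", r["label"]])


def ensure_dir(path: PathArg) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
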