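"""Synthetic cohort and clinical-note generator with known ground truth.

The generator emulates the structure of a maternal-care EHR extract: a
demographically mixed cohort of delivery patients, case/control outcome
records, and short typed clinical notes assembled from parameterized
sentence templates.  It injects, at configurable rates, the phenomena the
downstream pipeline must cope with — negated keyword uses ("patient is not
combative"), out-of-context keyword uses ("aggressive treatment options"),
heavily repeated template sentences, and true negative-descriptor
sentences whose per-patient probability follows a logistic model with
configurable odds ratios across demographic strata.

Truth is assigned at injection time and written next to every generated
sentence, never inferred afterwards, so every downstream stage has an
unambiguous oracle.  Identical configs (including the seed) produce
byte-identical corpora.
"""
from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import DEMOGRAPHIC_AXES, GeneratorConfig, NOTE_TYPES
from .errors import ConfigurationError, IntegrityError
from .types import (ClinicalNote, LABEL_NEGATIVE, LABEL_NO_KEYWORD,
                    LABEL_NOT_NEGATIVE, LABEL_OUT_OF_CONTEXT, OutcomeRecord,
                    Patient, SentenceTruth)

# ---------------------------------------------------------------------------
# sentence template bank

#: Keyword surface forms used in injected descriptor sentences; each matches
#: a seed root so the matcher and the truth agree by construction.
DESCRIPTOR_FORMS = (
    "combative", "agitated", "aggressive", "uncooperative", "noncompliant",
    "angry", "hysterical", "unpleasant", "defensive", "nonadherent",
)

DESCRIPTOR_TEMPLATES = (
    "Patient was {kw} with nursing staff throughout the shift.",
    "She remained {kw} and would not follow instructions from the team.",
    "Patient became {kw} when counseled about the medication schedule.",
    "Staff noted the patient to be {kw} during morning rounds.",
    "The patient was {kw} and demanding with the care team overnight.",
    "Patient {kw} and refused the recommended examination this morning.",
)

NEGATION_TEMPLATES = (
    "Patient is not {kw}.",
    "She denies feeling {kw} or anxious today.",
    "No anxiety, depression, or agitation noted on exam.",
    "Patient was calm and not {kw} during the examination.",
    "There were no episodes of {kw} behavior reported by staff.",
)
NEGATION_FORMS = ("combative", "agitated", "aggressive", "angry", "uncooperative")

OUT_OF_CONTEXT_TEMPLATES = (
    "We discussed aggressive treatment options with the family at length.",
    "Blood pressure remained resistant to the initial therapy this week.",
    "The infection was resistant to the first line of antibiotics.",
    "Providers reviewed several challenging differential diagnoses at rounds.",
    "Plan to confront remaining barriers to a safe discharge home.",
)

#: Heavily repeated boilerplate; the first carries a cooperative-family
#: token whose hit status depends on the validated lexicon.
REPEAT_TEMPLATES = (
    "Patient was alert and cooperative.",
    "A pleasant {age}-year-old female patient presenting for delivery.",
    "Vital signs stable and within normal limits.",
)

FILLER_TEMPLATES = (
    "Fetal heart tones reassuring on continuous monitoring.",
    "Cervical exam deferred at this time.",
    "Patient reports good fetal movement since this morning.",
    "Lungs clear to auscultation bilaterally with no wheezes.",
    "Abdomen gravid, soft, and nontender on palpation.",
    "Denies headache, visual changes, or epigastric pain.",
    "Membranes intact with no vaginal bleeding observed.",
    "Contractions mild and irregular over the past hour.",
    "Pain well controlled with the current epidural dosing.",
    "Plan to continue expectant management and routine labs.",
    "Group B strep screening collected and pending.",
    "History notable for one prior uncomplicated vaginal delivery.",
    "Reviewed the birth plan and answered all questions.",
    "Prenatal course followed at the outpatient clinic without complication.",
    "Patient ambulating in the hallway without assistance.",
    "Social work consulted for routine discharge planning.",
    "Anesthesia evaluated the patient for epidural placement.",
    "Blood type O positive with antibody screen negative on file.",
    "Urine protein trace on admission dipstick testing.",
    "Encouraged oral hydration and periodic position changes.",
    "Stable overnight.",
    "Doing well.",
)

#: Descriptor-family variant forms that seed the embedding corpus so roots
#: see their grammatical neighbours (also used by the demo validation).
VARIANT_FORMS = ("agitation", "aggression", "refusal", "resisting",
                 "noncompliance", "confrontational")
VARIANT_TEMPLATES = (
    "Episode of {kw} documented earlier by the night nurse.",
    "Chart review mentions prior {kw} during a previous admission.",
)

#: Optional trailing phrases appended to injected (non-boilerplate)
#: sentences so template classes vary lexically the way real notes do.
TAIL_PHRASES = (
    "", "this morning", "earlier today", "overnight", "per nursing report",
    "during the evaluation", "prior to rounds",
)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# cohort

def _sample_categorical(rng, levels: Sequence[str], probs: Dict[str, float], n: int):
    p = np.array([probs.get(l, 0.0) for l in levels])
    return rng.choice(len(levels), size=n, p=p / p.sum())


def generate_cohort(config: GeneratorConfig) -> Tuple[List[Patient], List[OutcomeRecord]]:
    """Sample the patient cohort and matching delivery outcome records.

    Outcome records are drawn so that applying the case/control rules
    recovers each patient's intended group: cases get an SMM code and/or a
    readmission within 42 days; controls clear every exclusion criterion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients: List[Patient] = []
    records: List[OutcomeRecord] = []
    if n == 0:
        return patients, records

    draws = {axis: _sample_categorical(rng, DEMOGRAPHIC_AXES[axis],
                                       config.demographic_mix[axis], n)
             for axis in DEMOGRAPHIC_AXES}
    is_case = rng.random(n) < config.case_fraction

    for i in range(n):
        pid = f"P{i:05d}"
        patients.append(Patient(
            patient_id=pid,
            age_group=DEMOGRAPHIC_AXES["age_group"][draws["age_group"][i]],
            race=DEMOGRAPHIC_AXES["race"][draws["race"][i]],
            insurance=DEMOGRAPHIC_AXES["insurance"][draws["insurance"][i]],
            outcome_group="case" if is_case[i] else "control",
        ))
        if is_case[i]:
            mode = rng.integers(0, 3)  # SMM only / readmission only / both
            records.append(OutcomeRecord(
                patient_id=pid,
                smm_codes=["SMM01"] if mode in (0, 2) else [],
                readmission_day=int(rng.integers(1, 43)) if mode in (1, 2) else None,
                birthweight_g=int(np.clip(rng.normal(3100, 500), 600, 5000)),
                gestation_weeks=float(np.round(np.clip(rng.normal(38.0, 2.5), 24, 42), 1)),
                instrument_assisted=bool(rng.random() < 0.15),
                nicu_admit=bool(rng.random() < 0.2),
            ))
        else:
            records.append(OutcomeRecord(
                patient_id=pid,
                smm_codes=[],
                readmission_day=None if rng.random() < 0.97 else int(rng.integers(43, 120)),
                birthweight_g=int(np.clip(rng.normal(3400, 350), 2500, 5000)),
                gestation_weeks=float(np.round(rng.uniform(37.0, 41.5), 1)),
                instrument_assisted=False,
                nicu_admit=False,
            ))
    return patients, records


def descriptor_probability(patient: Patient, config: GeneratorConfig) -> float:
    """P(at least one descriptor) for one patient under the logistic model."""
    base = config.descriptor_base_rate
    if base <= 0.0:
        return 0.0
    if base >= 1.0:
        return 1.0
    logit = math.log(base / (1.0 - base))
    for axis, ors in config.true_or_spec.items():
        level = getattr(patient, axis)
        if level in ors:
            logit += math.log(ors[level])
    return float(_expit(np.array(logit)))


def sample_descriptor_flags(patients: Sequence[Patient], config: GeneratorConfig,
                            seed: Optional[int] = None) -> Dict[str, bool]:
    """Draw each patient's true descriptor flag from the logistic model.

    This is the same draw :func:`generate_notes` uses to decide which
    patients receive injected descriptor sentences; exposing it directly
    supports cheap Monte-Carlo calibration studies without note text.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    ps = np.array([descriptor_probability(p, config) for p in patients])
    draws = rng.random(len(ps)) < ps
    return {p.patient_id: bool(d) for p, d in zip(patients, draws)}


# ---------------------------------------------------------------------------
# notes

def _render(template: str, rng, kw: Optional[str] = None,
            vary: bool = False) -> str:
    age = int(rng.integers(18, 45))
    text = template.format(kw=kw or "", age=age)
    if vary:
        tail = TAIL_PHRASES[rng.integers(0, len(TAIL_PHRASES))]
        if tail:
            text = f"{text[:-1]} {tail}."
    return text


def generate_notes(patients: Sequence[Patient], config: GeneratorConfig,
                   lexicon=None) -> Tuple[List[ClinicalNote], List[SentenceTruth]]:
    """Assemble typed notes from templates and record sentence-level truth.

    Every sentence gets a truth record labeled negative-descriptor,
    not-negative, out-of-context, or no-keyword.  Descriptor sentences are
    injected only for patients whose flag from the logistic model is true;
    a patient's true flag therefore equals the OR over their sentences'
    negative-descriptor labels.  ``lexicon`` must be non-empty (seeds plus
    roots suffice) because injected keyword forms are drawn to match it.
    """
    config.validate()
    if lexicon is not None and not getattr(lexicon, "seeds", None):
        raise ConfigurationError("lexicon must be non-empty")
    rng = np.random.default_rng(config.seed + 7)
    flags = sample_descriptor_flags(patients, config)

    notes: List[ClinicalNote] = []
    truths: List[SentenceTruth] = []
    note_counter = 0
    for p in patients:
        n_notes = 1 + int(rng.poisson(max(0.0, config.notes_per_patient_mean - 1)))
        encounter_id = f"E{p.patient_id[1:]}"
        # descriptor sentences for flagged patients: at least one, occasionally more
        n_desc = 0
        if flags[p.patient_id]:
            n_desc = 1 + int(rng.poisson(config.descriptor_sentence_rate))
        desc_slots = sorted(rng.integers(0, n_notes, size=n_desc).tolist())

        for j in range(n_notes):
            note_id = f"N{note_counter:06d}"
            note_counter += 1
            note_type = NOTE_TYPES[rng.integers(0, len(NOTE_TYPES))]
            day = int(rng.integers(0, 3))
            hour = int(rng.integers(6, 22))
            timestamp = f"2019-06-{10 + day:02d}T{hour:02d}:00:00"
            k = 1 + int(rng.poisson(max(0.0, config.sentences_per_note_mean - 1)))
            texts: List[str] = []
            labels: List[tuple] = []
            for _ in range(k):
                u = rng.random()
                if u < config.template_repeat_rate:
                    t = REPEAT_TEMPLATES[rng.integers(0, len(REPEAT_TEMPLATES))]
                    text = _render(t, rng)
                    kw = "cooperative" if "cooperative" in t else None
                    labels.append((LABEL_NOT_NEGATIVE if kw else LABEL_NO_KEYWORD, kw))
                elif u < config.template_repeat_rate + config.negation_rate:
                    t = NEGATION_TEMPLATES[rng.integers(0, len(NEGATION_TEMPLATES))]
                    kw = NEGATION_FORMS[rng.integers(0, len(NEGATION_FORMS))]
                    text = _render(t, rng, kw, vary=True)
                    kw = "agitation" if "{kw}" not in t else kw
                    labels.append((LABEL_NOT_NEGATIVE, kw))
                elif u < (config.template_repeat_rate + config.negation_rate
                          + config.out_of_context_rate):
                    t = OUT_OF_CONTEXT_TEMPLATES[rng.integers(0, len(OUT_OF_CONTEXT_TEMPLATES))]
                    text = _render(t, rng, vary=True)
                    labels.append((LABEL_OUT_OF_CONTEXT, None))
                elif u < (config.template_repeat_rate + config.negation_rate
                          + config.out_of_context_rate + config.variant_rate):
                    t = VARIANT_TEMPLATES[rng.integers(0, len(VARIANT_TEMPLATES))]
                    kw = VARIANT_FORMS[rng.integers(0, len(VARIANT_FORMS))]
                    text = _render(t, rng, kw, vary=True)
                    labels.append((LABEL_OUT_OF_CONTEXT, kw))
                else:
                    t = FILLER_TEMPLATES[rng.integers(0, len(FILLER_TEMPLATES))]
                    text = _render(t, rng)
                    labels.append((LABEL_NO_KEYWORD, None))
                texts.append(text)
            for _ in range(desc_slots.count(j)):
                t = DESCRIPTOR_TEMPLATES[rng.integers(0, len(DESCRIPTOR_TEMPLATES))]
                kw = DESCRIPTOR_FORMS[rng.integers(0, len(DESCRIPTOR_FORMS))]
                pos = int(rng.integers(0, len(texts) + 1))
                texts.insert(pos, _render(t, rng, kw, vary=True))
                labels.insert(pos, (LABEL_NEGATIVE, kw))
            note = ClinicalNote(note_id=note_id, patient_id=p.patient_id,
                                encounter_id=encounter_id, note_type=note_type,
                                timestamp=timestamp, text=" ".join(texts))
            notes.append(note)
            for pos, (label, kw) in enumerate(labels):
                truths.append(SentenceTruth(
                    sentence_id=f"{note_id}:{pos}", note_id=note_id,
                    patient_id=p.patient_id, label=label, keyword=kw))
    return notes, truths


def truth_summary(truths: Sequence[SentenceTruth], patients: Sequence[Patient]) -> Dict:
    """Per-stratum patient-level descriptor prevalence from the truth records.

    A patient's flag is the OR over their sentences' negative-descriptor
    labels.  Raises :class:`IntegrityError` for truth rows naming unknown
    patients; within every axis the stratum counts partition the cohort.
    """
    known = {p.patient_id for p in patients}
    flagged = set()
    for t in truths:
        if t.patient_id not in known:
            raise IntegrityError(f"truth references unknown patient {t.patient_id}")
        if t.label == LABEL_NEGATIVE:
            flagged.add(t.patient_id)
    summary: Dict[str, Dict[str, dict]] = {}
    axes = dict(DEMOGRAPHIC_AXES, outcome_group=("case", "control"))
    for axis, levels in axes.items():
        summary[axis] = {}
        for level in levels:
            members = [p for p in patients if getattr(p, axis) == level]
            n_with = sum(p.patient_id in flagged for p in members)
            summary[axis][level] = {
                "n_patients": len(members),
                "n_with_descriptor": n_with,
                "prevalence": n_with / len(members) if members else 0.0,
            }
    summary["overall"] = {
        "n_patients": len(patients),
        "n_with_descriptor": len(flagged),
        "prevalence": len(flagged) / len(patients) if patients else 0.0,
    }
    return summary
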