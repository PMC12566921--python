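"""Domain records passed between pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import AGE_GROUPS, INSURANCE_TYPES, NOTE_TYPES, OUTCOME_GROUPS, RACES
from .errors import InputError

#: Sentence-level truth / annotation labels.
LABEL_NEGATIVE = "negative_descriptor"
LABEL_NOT_NEGATIVE = "not_negative_descriptor"
LABEL_OUT_OF_CONTEXT = "out_of_context"
LABEL_NO_KEYWORD = "no_keyword"
SENTENCE_LABELS = (LABEL_NEGATIVE, LABEL_NOT_NEGATIVE, LABEL_OUT_OF_CONTEXT)


@dataclass(frozen=True)
class Patient:
    patient_id: str
    age_group: str
    race: str
    insurance: str
    outcome_group: str

    def __post_init__(self):
        if self.age_group not in AGE_GROUPS:
            raise InputError(f"unknown age group {self.age_group!r}")
        if self.race not in RACES:
            raise InputError(f"unknown race {self.race!r}")
        if self.insurance not in INSURANCE_TYPES:
            raise InputError(f"unknown insurance {self.insurance!r}")
        if self.outcome_group not in OUTCOME_GROUPS:
            raise InputError(f"unknown outcome group {self.outcome_group!r}")


@dataclass
class OutcomeRecord:
    """Delivery-encounter outcomes used for case/control assignment."""

    patient_id: str
    smm_codes: list = field(default_factory=list)
    readmission_day: Optional[int] = None  # days post-delivery; None = no readmission
    birthweight_g: int = 3300
    gestation_weeks: float = 39.0
    instrument_assisted: bool = False
    nicu_admit: bool = False

    def __post_init__(self):
        if self.readmission_day is not None and self.readmission_day < 0:
            raise InputError("readmission_day must be >= 0")
        if self.birthweight_g <= 0:
            raise InputError("birthweight_g must be > 0")


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    encounter_id: str
    note_type: str
    timestamp: str  # ISO-8601
    text: str

    def __post_init__(self):
        if self.note_type not in NOTE_TYPES:
            raise InputError(
                f"note_type {self.note_type!r} is not one of the five selected types"
            )
        if not self.text:
            raise InputError("note text must be non-empty")


@dataclass(frozen=True)
class KeywordHit:
    """A token matched against the lexicon, with its provenance."""

    token: str
    term: str  # the lexicon root or validated term that matched
    start: int  # character offset of the token in the sentence


@dataclass
class Sentence:
    sentence_id: str
    note_id: str
    position: int
    text: str
    token_count: int
    keyword_hits: list = field(default_factory=list)


@dataclass
class SentenceTruth:
    """Ground-truth record written by the generator at injection time."""

    sentence_id: str
    note_id: str
    patient_id: str
    label: str  # one of SENTENCE_LABELS or LABEL_NO_KEYWORD
    keyword: Optional[str] = None  # injected keyword, when any


@dataclass
class AnnotationRecord:
    sentence_id: str
    label_a: Optional[str] = None
    label_b: Optional[str] = None
    final_label: Optional[str] = None
    excluded_from_modeling: bool = False


@dataclass
class PatientRollup:
    """Per-patient aggregation of note and sentence-level results."""

    patient_id: str
    age_group: str
    race: str
    insurance: str
    outcome_group: str
    n_notes: int = 0
    n_keyword_notes: int = 0
    n_descriptor_notes: int = 0

    @property
    def has_descriptor(self) -> bool:
        return self.n_descriptor_notes >= 1
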