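"""Configuration dataclasses and the controlled vocabularies they draw on.

The categorical axes (age group, race, insurance, outcome group) and the
five history-related note types are fixed study vocabulary; everything else
is tunable.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

from .errors import ConfigurationError

AGE_GROUPS = ("18-29", "30-44", "45+")
RACES = ("Black", "White", "Other")
INSURANCE_TYPES = ("Medicare/Medicaid", "Commercial", "Self-pay")
OUTCOME_GROUPS = ("case", "control")

#: The five history-related clinical note types the cohort is restricted to.
NOTE_TYPES = (
    "history and physical",
    "review of systems",
    "history of present illness",
    "physical examination",
    "triage",
)

#: Demographic axes in the order tables and models report them.
DEMOGRAPHIC_AXES = {
    "age_group": AGE_GROUPS,
    "race": RACES,
    "insurance": INSURANCE_TYPES,
}

#: Reference levels for odds-ratio models (the level with OR fixed to 1).
REFERENCE_LEVELS = {
    "age_group": "45+",
    "race": "White",
    "insurance": "Commercial",
    "outcome_group": "control",
}


def _check_probability_vector(name: str, probs: dict) -> None:
    total = sum(probs.values())
    if any(p < 0 for p in probs.values()) or abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"probabilities for {name} must be non-negative and sum to 1 (got {total})"
        )


@dataclass
class GeneratorConfig:
    """Controls the synthetic cohort and note corpus.

    Descriptor presence is assigned per patient from a logistic model:
    the reference profile (45+, White, Commercial, control) has probability
    ``descriptor_base_rate`` and each non-reference level multiplies the
    odds by its entry in ``true_or_spec``.  Defaults follow the adjusted
    odds ratios and marginal mixes of the study population the generator
    emulates.
    """

    n_patients: int = 1000
    demographic_mix: dict = field(default_factory=lambda: {
        "age_group": {"18-29": 0.43, "30-44": 0.55, "45+": 0.02},
        "race": {"Black": 0.60, "White": 0.20, "Other": 0.20},
        "insurance": {"Medicare/Medicaid": 0.53, "Commercial": 0.44, "Self-pay": 0.03},
    })
    case_fraction: float = 0.075
    descriptor_base_rate: float = 0.05
    true_or_spec: dict = field(default_factory=lambda: {
        "age_group": {"18-29": 0.66, "30-44": 0.68},
        "race": {"Black": 2.05, "Other": 0.97},
        "insurance": {"Medicare/Medicaid": 1.59, "Self-pay": 1.42},
        "outcome_group": {"case": 1.40},
    })
    notes_per_patient_mean: float = 3.0  # notes per patient = 1 + Poisson(mean)
    sentences_per_note_mean: float = 6.0
    negation_rate: float = 0.10
    out_of_context_rate: float = 0.10
    variant_rate: float = 0.03  # historical-mention keyword variants
    template_repeat_rate: float = 0.25
    descriptor_sentence_rate: float = 0.5  # extra descriptor sentences per flagged patient
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        for axis, probs in self.demographic_mix.items():
            if axis not in DEMOGRAPHIC_AXES:
                raise ConfigurationError(f"unknown demographic axis {axis!r}")
            if set(probs) - set(DEMOGRAPHIC_AXES[axis]):
                raise ConfigurationError(f"unknown level in mix for {axis}")
            _check_probability_vector(axis, probs)
        for rate_name in ("case_fraction", "descriptor_base_rate", "negation_rate",
                          "out_of_context_rate", "variant_rate", "template_repeat_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{rate_name} must be in [0, 1]")
        for axis, ors in self.true_or_spec.items():
            if any(r <= 0 for r in ors.values()):
                raise ConfigurationError(f"odds ratios for {axis} must be > 0")


@dataclass
class EmbeddingConfig:
    """Word2Vec training settings (window 5, all words kept by default)."""

    algorithm: str = "skip-gram"  # or "cbow"
    window: int = 5
    min_count: int = 1
    vector_dim: int = 100
    epochs: int = 10
    negative: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def validate(self) -> None:
        if self.algorithm not in ("skip-gram", "cbow"):
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.window < 1 or self.min_count < 1 or self.vector_dim < 2:
            raise ConfigurationError(
                "window >= 1, min_count >= 1, vector_dim >= 2 required"
            )


@dataclass
class FilterConfig:
    """Sentence length filter and review-set reduction settings.

    Retention is inclusive: a sentence survives iff
    ``min_words <= token_count <= max_words``.  In ``percentile`` mode the
    cap is the nearest-rank 95th percentile of corpus token counts.
    """

    min_words: int = 3
    max_words: int = 27
    max_words_mode: str = "fixed"  # or "percentile"
    percentile: float = 95.0
    dedup_min_repeats: int = 10
    dedup_whitelist: tuple = (
        r"\balert and cooperative\b",
        r"\bpleasant\b.*\bpatient\b",
        r"\bpatient\b.*\bpleasant\b",
    )

    def validate(self) -> None:
        if self.min_words < 1:
            raise ConfigurationError("min_words must be >= 1")
        if self.max_words_mode == "fixed" and self.max_words < self.min_words:
            raise ConfigurationError("max_words must be >= min_words")
        if self.max_words_mode not in ("fixed", "percentile"):
            raise ConfigurationError(f"unknown max_words_mode {self.max_words_mode!r}")


@dataclass
class FeatureSpec:
    """Sentence featurization: bag of n-grams over the whole sentence by
    default, optionally restricted to a token window around keyword hits."""

    representation: str = "binary"  # binary | counts | tfidf
    ngram_range: tuple = (1, 2)
    min_document_frequency: int = 2
    keyword_window: Optional[int] = None  # tokens each side of a hit; None = whole sentence

    def validate(self) -> None:
        if self.representation not in ("binary", "counts", "tfidf"):
            raise ConfigurationError(f"unknown representation {self.representation!r}")
        lo, hi = self.ngram_range
        if lo > hi or self.min_document_frequency < 1:
            raise ConfigurationError("ngram_range lower <= upper and min_df >= 1 required")


@dataclass
class ModelSpec:
    """Classifier family plus hyperparameter search strategy."""

    family: str = "elastic_net_logistic"  # logistic | random_forest | svm
    search: str = "auto"  # grid | bayesian | auto (grid for linear, bayesian otherwise)
    cv_folds: int = 5
    seed: int = 0
    search_budget: int = 15  # evaluations for the Bayesian search
    search_space: Optional[dict] = None  # override the family default grid

    FAMILIES = ("elastic_net_logistic", "logistic", "random_forest", "svm")

    def validate(self) -> None:
        if self.family not in self.FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        if self.search not in ("grid", "bayesian", "auto"):
            raise ConfigurationError(f"unknown search strategy {self.search!r}")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


@dataclass
class SplitSpec:
    """Train/test split and cross-validation fold layout."""

    test_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0
    stratify_by_label: bool = True

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


@dataclass
class CaseControlRule:
    """Case/control assignment: case = any severe-maternal-morbidity code or
    readmission within the window (day 42 inclusive); control additionally
    requires that none of the low-risk exclusions fire."""

    smm_code_list: tuple = ("SMM01", "SMM02", "SMM03")  # user-supplied in practice
    readmission_window_days: int = 42
    min_birthweight_g: int = 2500
    min_gestation_weeks: float = 37.0
    exclude_instrument_assisted: bool = True
    exclude_nicu_admit: bool = True

    def validate(self) -> None:
        if self.readmission_window_days <= 0:
            raise ConfigurationError("readmission_window_days must be > 0")
        if not self.smm_code_list:
            raise ConfigurationError("smm_code_list must be non-empty")


def config_hash(*configs) -> str:
    """Stable short hash over one or more config dataclasses."""
    payload = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a single global seed out to a per-stage seed (< 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
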