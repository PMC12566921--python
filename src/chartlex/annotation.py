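"""Dual-reviewer annotation: conservative disagreement resolution,
inter-annotator agreement, and train/test splitting.

Each reviewed sentence gets one of three labels — negative descriptor,
not a negative descriptor, or out-of-context (the keyword does not
describe the patient; negations land here or in not-negative).  When the
two reviewers disagree on the *presence* of a negative descriptor the
sentence is conservatively relabeled out-of-context and excluded from
modeling; disagreements between the two non-negative labels resolve to
out-of-context without exclusion.
"""
from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

from .config import SplitSpec
from .errors import ConfigurationError, IncompleteAnnotationError
from .types import (AnnotationRecord, LABEL_NEGATIVE, LABEL_OUT_OF_CONTEXT,
                    SENTENCE_LABELS)

logger = logging.getLogger(__name__)


def resolve_labels(record: AnnotationRecord) -> AnnotationRecord:
    """Fill ``final_label`` and ``excluded_from_modeling`` in place.

    Agreement keeps the agreed label.  A split on descriptor presence
    (exactly one reviewer chose negative descriptor) resolves to
    out-of-context with the exclusion flag set.
    """
    if record.label_a is None or record.label_b is None:
        raise IncompleteAnnotationError(
            f"sentence {record.sentence_id}: both reviewer labels required")
    for lab in (record.label_a, record.label_b):
        if lab not in SENTENCE_LABELS:
            raise IncompleteAnnotationError(
                f"sentence {record.sentence_id}: unknown label {lab!r}")
    if record.label_a == record.label_b:
        record.final_label = record.label_a
        record.excluded_from_modeling = False
    elif (record.label_a == LABEL_NEGATIVE) != (record.label_b == LABEL_NEGATIVE):
        record.final_label = LABEL_OUT_OF_CONTEXT
        record.excluded_from_modeling = True
    else:  # not-negative vs out-of-context: no presence dispute
        record.final_label = LABEL_OUT_OF_CONTEXT
        record.excluded_from_modeling = False
    return record


def resolve_all(records: Sequence[AnnotationRecord]) -> Tuple[List[AnnotationRecord], Dict]:
    """Resolve every record; summary counts agreements and exclusions."""
    for r in records:
        resolve_labels(r)
    n_excluded = sum(r.excluded_from_modeling for r in records)
    n_disagreed = sum(r.label_a != r.label_b for r in records)
    return list(records), {
        "n_records": len(records),
        "n_disagreements": n_disagreed,
        "n_excluded": n_excluded,
    }


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with marginal-product
    expected agreement.

    Both raters constant and identical gives p_e = 1; kappa is then 1 by
    convention (logged), since agreement is perfect.
    """
    if len(labels_a) != len(labels_b):
        raise ConfigurationError("label sequences must have equal length")
    n = len(labels_a)
    if n < 2:
        raise ConfigurationError("kappa needs at least 2 items")
    cats = sorted(set(labels_a) | set(labels_b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(labels_a, labels_b):
        table[idx[a], idx[b]] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        logger.info("degenerate kappa: both raters constant; returning 1.0")
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_binary_presence(records: Sequence[AnnotationRecord]) -> float:
    """Kappa on the descriptor-presence dimension (negative vs rest)."""
    a = [r.label_a == LABEL_NEGATIVE for r in records]
    b = [r.label_b == LABEL_NEGATIVE for r in records]
    return cohen_kappa(a, b)


def split_data(records: Sequence[AnnotationRecord],
               spec: SplitSpec | None = None) -> Dict:
    """80/20 train-test split plus cross-validation fold assignments.

    Returns ``{"train_ids", "test_ids", "folds"}`` where folds maps each
    training sentence id to its fold index.  Stratified by final label
    when the spec asks for it; deterministic under the spec seed.
    """
    spec = spec or SplitSpec()
    spec.validate()
    records = [r for r in records if not r.excluded_from_modeling]
    if len(records) < spec.cv_folds:
        raise ConfigurationError("fewer records than cv folds")
    ids = np.array([r.sentence_id for r in records])
    labels = np.array([r.final_label == LABEL_NEGATIVE for r in records], dtype=int)
    stratify = labels if spec.stratify_by_label else None
    train_ids, test_ids, train_y, _ = train_test_split(
        ids, labels, test_size=spec.test_fraction,
        random_state=spec.seed, stratify=stratify)
    if spec.stratify_by_label and len(np.unique(train_y)) > 1:
        splitter = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                                   random_state=spec.seed)
        fold_iter = splitter.split(train_ids, train_y)
    else:
        splitter = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
        fold_iter = splitter.split(train_ids)
    folds = {}
    for fold, (_, val_idx) in enumerate(fold_iter):
        for i in val_idx:
            folds[str(train_ids[i])] = fold
    return {"train_ids": [str(i) for i in train_ids],
            "test_ids": [str(i) for i in test_ids],
            "folds": folds}
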