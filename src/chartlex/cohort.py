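"""Patient-level analysis: case/control assignment, rollups of sentence
predictions, stratified prevalence tables with chi-square tests, and
unadjusted/adjusted odds-ratio models.

Case = any severe-maternal-morbidity code or postpartum readmission within
the window (day 42 inclusive).  Control = no case criterion and none of
the low-risk exclusions (birthweight < 2,500 g, gestation < 37 weeks,
instrument-assisted delivery, NICU admission).  Patients failing both are
excluded from the cohort.

Odds-ratio models regress per-patient descriptor presence on age group,
race, insurance and pregnancy type over the full cohort, with reference
levels 45+, White, Commercial and control; unadjusted ORs come from
single-covariate fits, adjusted ORs from the joint fit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import CaseControlRule, DEMOGRAPHIC_AXES, REFERENCE_LEVELS
from .errors import IntegrityError
from .types import (ClinicalNote, LABEL_NEGATIVE, OutcomeRecord, Patient,
                    PatientRollup)

logger = logging.getLogger(__name__)

#: Significance bands reported next to odds ratios.
P_BANDS = ((0.001, "p<0.001"), (0.01, "p<0.01"), (0.05, "p<0.05"), (0.1, "p<0.1"))


def p_band(p: float) -> str:
    for cut, label in P_BANDS:
        if p < cut:
            return label
    return ""


# ---------------------------------------------------------------------------
# case/control

def assign_case_control(records: Sequence[OutcomeRecord],
                        rule: Optional[CaseControlRule] = None) -> Dict[str, str]:
    """Map patient id -> case / control / excluded.

    Case fires on any SMM code or a readmission at or before the window
    boundary.  A non-case with any low-risk exclusion is dropped from the
    cohort ("excluded") rather than kept as a contaminated control.
    """
    rule = rule or CaseControlRule()
    rule.validate()
    smm = set(rule.smm_code_list)
    out = {}
    for rec in records:
        is_case = bool(set(rec.smm_codes) & smm) or (
            rec.readmission_day is not None
            and rec.readmission_day <= rule.readmission_window_days)
        if is_case:
            out[rec.patient_id] = "case"
            continue
        excluded = (
            rec.birthweight_g < rule.min_birthweight_g
            or rec.gestation_weeks < rule.min_gestation_weeks
            or (rule.exclude_instrument_assisted and rec.instrument_assisted)
            or (rule.exclude_nicu_admit and rec.nicu_admit)
        )
        out[rec.patient_id] = "excluded" if excluded else "control"
    return out


# ---------------------------------------------------------------------------
# rollup

def rollup(patients: Sequence[Patient], notes: Sequence[ClinicalNote],
           sentences: Sequence, labels: Mapping[str, str]) -> List[PatientRollup]:
    """Aggregate sentence labels to note and patient level.

    ``labels`` maps sentence id -> predicted/true label.  A note counts as
    a keyword note when any of its sentences carries a keyword hit, and as
    a descriptor note when any sentence is labeled negative-descriptor.
    Orphan sentences (unknown note) and notes with unknown patients raise
    :class:`IntegrityError`.
    """
    note_by_id = {n.note_id: n for n in notes}
    patient_by_id = {p.patient_id: p for p in patients}
    for n in notes:
        if n.patient_id not in patient_by_id:
            raise IntegrityError(f"note {n.note_id} references unknown patient")

    kw_notes, desc_notes = set(), set()
    for s in sentences:
        if s.note_id not in note_by_id:
            raise IntegrityError(f"sentence {s.sentence_id} references unknown note")
        if s.keyword_hits:
            kw_notes.add(s.note_id)
        if labels.get(s.sentence_id) == LABEL_NEGATIVE:
            desc_notes.add(s.note_id)

    rollups = {p.patient_id: PatientRollup(
        patient_id=p.patient_id, age_group=p.age_group, race=p.race,
        insurance=p.insurance, outcome_group=p.outcome_group)
        for p in patients}
    for n in notes:
        r = rollups[n.patient_id]
        r.n_notes += 1
        r.n_keyword_notes += n.note_id in kw_notes
        r.n_descriptor_notes += n.note_id in desc_notes
    return list(rollups.values())


# ---------------------------------------------------------------------------
# stratified tables

@dataclass
class StratifiedTable:
    """Counts and percentages by stratum, split on descriptor presence."""

    table: pd.DataFrame  # rows: (axis, stratum) with count/pct columns
    p_values: Dict[str, float]
    n_without: int
    n_with: int
    flags: Dict[str, str] = field(default_factory=dict)


def prevalence_table(rollups: Sequence[PatientRollup],
                     axes: Sequence[str] = tuple(DEMOGRAPHIC_AXES) + ("outcome_group",)
                     ) -> StratifiedTable:
    """Characteristics of patients with vs without a negative descriptor.

    Percentages are column percentages to one decimal.  Each axis gets a
    chi-square test without continuity correction; a 2x2 axis with any
    expected cell below 5 switches to Fisher's exact test, larger axes
    with small cells keep chi-square but are flagged.
    """
    axis_levels = dict(DEMOGRAPHIC_AXES, outcome_group=("case", "control"))
    with_d = [r for r in rollups if r.has_descriptor]
    without_d = [r for r in rollups if not r.has_descriptor]
    rows = []
    p_values, flags = {}, {}
    for axis in axes:
        levels = axis_levels[axis]
        counts = np.zeros((len(levels), 2), dtype=int)
        for j, group in enumerate((without_d, with_d)):
            for r in group:
                counts[levels.index(getattr(r, axis)), j] += 1
        for i, level in enumerate(levels):
            rows.append({
                "axis": axis, "stratum": level,
                "count_without": int(counts[i, 0]),
                "pct_without": round(100.0 * counts[i, 0] / max(1, len(without_d)), 1),
                "count_with": int(counts[i, 1]),
                "pct_with": round(100.0 * counts[i, 1] / max(1, len(with_d)), 1),
            })
        nonzero = counts[counts.sum(axis=1) > 0]
        if nonzero.shape[0] < 2 or nonzero.shape[0] < counts.shape[0]:
            logger.warning("axis %s has empty strata; they are excluded from chi-square", axis)
        if nonzero.shape[0] < 2 or min(len(with_d), len(without_d)) == 0:
            p_values[axis] = float("nan")
            continue
        chi2, p, _, expected = stats.chi2_contingency(nonzero, correction=False)
        if (expected < 5).any():
            if nonzero.shape == (2, 2):
                _, p = stats.fisher_exact(nonzero)
                flags[axis] = "fisher_exact"
            else:
                flags[axis] = "small_expected_cells"
        p_values[axis] = float(p)
    return StratifiedTable(table=pd.DataFrame(rows), p_values=p_values,
                           n_without=len(without_d), n_with=len(with_d),
                           flags=flags)


def chi_square(table: np.ndarray) -> tuple:
    """Chi-square statistic and p without continuity correction."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# odds ratios

@dataclass
class ORResult:
    axis: str
    level: str
    reference: str
    or_unadjusted: Optional[float]
    p_unadjusted: Optional[float]
    or_adjusted: Optional[float]
    p_adjusted: Optional[float]
    ci_unadjusted: Optional[tuple] = None  # 95% Wald interval on the OR scale
    ci_adjusted: Optional[tuple] = None
    band_adjusted: str = ""
    estimable: bool = True


def two_by_two_or(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio ad/bc for a 2x2 table
    [[exposed-with, exposed-without], [unexposed-with, unexposed-without]]."""
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def _fit_logit(df: pd.DataFrame, formula: str):
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    return model.fit()


def _term_map(axis: str, reference: str) -> str:
    return f"C(Q('{axis}'), Treatment('{reference}'))"


def odds_ratios(rollups: Sequence[PatientRollup],
                covariates: Sequence[str] = ("age_group", "race", "insurance",
                                             "outcome_group"),
                references: Optional[Mapping[str, str]] = None) -> List[ORResult]:
    """Unadjusted and adjusted odds ratios of descriptor presence.

    The outcome is ``has_descriptor`` over the *full* cohort passed in
    (patients without keyword notes count as descriptor-free).  Levels with
    all-0 or all-1 outcomes are flagged non-estimable rather than reported
    with a runaway estimate.
    """
    references = dict(references or REFERENCE_LEVELS)
    df = pd.DataFrame([{
        "y": int(r.has_descriptor),
        **{c: getattr(r, c) for c in covariates},
    } for r in rollups])
    if df.empty or df["y"].nunique() < 2:
        raise IntegrityError("odds ratios need both outcome classes present")

    # detect separation per level up front
    separated = set()
    for axis in covariates:
        for level, grp in df.groupby(axis, observed=True)["y"]:
            if grp.nunique() < 2:
                separated.add((axis, level))
                logger.warning("separation: %s=%s has constant outcome", axis, level)

    adjusted_formula = "y ~ " + " + ".join(_term_map(a, references[a]) for a in covariates)
    adj_fit = _fit_logit(df, adjusted_formula)

    results = []
    for axis in covariates:
        ref = references[axis]
        unadj_fit = _fit_logit(df, f"y ~ {_term_map(axis, ref)}")
        levels = [l for l in df[axis].unique() if l != ref]
        for level in sorted(levels):
            pname = f"{_term_map(axis, references[axis])}[T.{level}]"
            estimable = (axis, level) not in separated and (axis, ref) not in separated
            if estimable and pname in unadj_fit.params.index:
                or_u = float(np.exp(unadj_fit.params[pname]))
                p_u = float(unadj_fit.pvalues[pname])
                or_a = float(np.exp(adj_fit.params[pname]))
                p_a = float(adj_fit.pvalues[pname])
                ci_u = tuple(np.exp(unadj_fit.conf_int().loc[pname]).tolist())
                ci_a = tuple(np.exp(adj_fit.conf_int().loc[pname]).tolist())
            else:
                or_u = p_u = or_a = p_a = ci_u = ci_a = None
                estimable = False
            results.append(ORResult(
                axis=axis, level=level, reference=ref,
                or_unadjusted=or_u, p_unadjusted=p_u,
                or_adjusted=or_a, p_adjusted=p_a,
                ci_unadjusted=ci_u, ci_adjusted=ci_a,
                band_adjusted=p_band(p_a) if p_a is not None else "",
                estimable=estimable))
    return results


def or_results_frame(results: Sequence[ORResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": f"{r.axis}={r.level}", "reference": r.reference,
        "or_unadj": r.or_unadjusted, "or_adj": r.or_adjusted,
        "p_unadj": r.p_unadjusted, "p_adj": r.p_adjusted,
        "p_band": r.band_adjusted, "estimable": r.estimable,
    } for r in results])
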