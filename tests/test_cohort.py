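"""Case/control rules, rollups, stratified tables, odds-ratio engine."""
import numpy as np
import pytest

from chartlex import (CaseControlRule, ClinicalNote, OutcomeRecord, Patient,
                      PatientRollup, Sentence, assign_case_control, chi_square,
                      odds_ratios, prevalence_table, rollup, two_by_two_or,
                      LABEL_NEGATIVE, LABEL_NOT_NEGATIVE)
from chartlex.errors import IntegrityError


def _rec(**kw):
    base = dict(patient_id="P1", smm_codes=[], readmission_day=None,
                birthweight_g=3300, gestation_weeks=39.0,
                instrument_assisted=False, nicu_admit=False)
    base.update(kw)
    return OutcomeRecord(**base)


@pytest.mark.parametrize("record,expected", [
    (_rec(readmission_day=42), "case"),                      # window inclusive
    (_rec(readmission_day=43), "control"),                   # just outside
    (_rec(smm_codes=["SMM02"]), "case"),
    (_rec(birthweight_g=2400), "excluded"),                  # low birthweight
    (_rec(gestation_weeks=36.5), "excluded"),                # preterm
    (_rec(instrument_assisted=True), "excluded"),
    (_rec(nicu_admit=True), "excluded"),
    (_rec(), "control"),
    (_rec(smm_codes=["SMM01"], birthweight_g=2000), "case"), # case trumps exclusions
])
def test_case_control_rules(record, expected):
    assert assign_case_control([record], CaseControlRule())["P1"] == expected


# --------------------------------------------------------------------- rollup

def _mini_world():
    patients = [Patient("P1", "18-29", "Black", "Commercial", "control"),
                Patient("P2", "30-44", "White", "Commercial", "control")]
    notes = [ClinicalNote(f"N{i}", "P1", "E1", "triage",
                          "2019-06-10T08:00:00", "Text here.") for i in range(3)]
    notes.append(ClinicalNote("N3", "P2", "E2", "triage",
                              "2019-06-10T09:00:00", "Text here."))
    sentences = [Sentence("N0:0", "N0", 0, "Patient was combative.", 3),
                 Sentence("N1:0", "N1", 0, "Doing well.", 2),
                 Sentence("N3:0", "N3", 0, "Patient refused meds.", 3)]
    from chartlex import KeywordHit
    sentences[0].keyword_hits = [KeywordHit("combative", "combative", 12)]
    sentences[2].keyword_hits = [KeywordHit("refused", "refus", 8)]
    labels = {"N0:0": LABEL_NEGATIVE, "N1:0": LABEL_NOT_NEGATIVE,
              "N3:0": LABEL_NOT_NEGATIVE}
    return patients, notes, sentences, labels


def test_rollup_counts_and_flags():
    patients, notes, sentences, labels = _mini_world()
    rolls = {r.patient_id: r for r in rollup(patients, notes, sentences, labels)}
    r1 = rolls["P1"]
    assert (r1.n_notes, r1.n_keyword_notes, r1.n_descriptor_notes) == (3, 1, 1)
    assert r1.has_descriptor
    r2 = rolls["P2"]
    assert (r2.n_keyword_notes, r2.n_descriptor_notes) == (1, 0)
    assert not r2.has_descriptor
    for r in rolls.values():
        assert r.n_descriptor_notes <= r.n_keyword_notes <= r.n_notes


def test_rollup_orphan_sentence_rejected():
    patients, notes, sentences, labels = _mini_world()
    sentences.append(Sentence("NX:0", "NX", 0, "orphan", 1))
    with pytest.raises(IntegrityError):
        rollup(patients, notes, sentences, labels)


def test_rollup_recovers_generator_truth(small_corpus):
    """Feeding the generator's own truth labels through the rollup gives
    patient flags identical to the injected flags."""
    from chartlex import extract_sentences, sample_descriptor_flags
    patients = small_corpus["patients"]
    notes = small_corpus["notes"]
    sentences = extract_sentences(notes)
    labels = {t.sentence_id: t.label for t in small_corpus["truths"]}
    rolls = rollup(patients, notes, sentences, labels)
    # flags drawn by the generator itself
    import chartlex
    cfg = chartlex.GeneratorConfig(n_patients=120, seed=11)
    flags = sample_descriptor_flags(patients, cfg)
    for r in rolls:
        assert r.has_descriptor == flags[r.patient_id]


# --------------------------------------------------------------------- tables

def _rollup(pid, race="White", age="30-44", ins="Commercial", grp="control",
            desc=False, kw=True):
    return PatientRollup(patient_id=pid, age_group=age, race=race,
                         insurance=ins, outcome_group=grp, n_notes=2,
                         n_keyword_notes=int(kw),
                         n_descriptor_notes=int(desc))


def test_prevalence_table_counts_percentages_and_conservation():
    rolls = ([_rollup(f"a{i}", race="Black", desc=True) for i in range(3)]
             + [_rollup(f"b{i}", race="White", desc=True) for i in range(1)]
             + [_rollup(f"c{i}", race="Black", desc=False) for i in range(2)]
             + [_rollup(f"d{i}", race="White", desc=False) for i in range(4)])
    t = prevalence_table(rolls, axes=("race",))
    assert t.n_with == 4 and t.n_without == 6
    rows = {r["stratum"]: r for _, r in t.table.iterrows()}
    assert rows["Black"]["count_with"] == 3
    assert rows["Black"]["pct_with"] == 75.0
    assert rows["White"]["pct_without"] == round(100 * 4 / 6, 1)
    # with + without equals stratum totals
    for lvl in ("Black", "White"):
        total = sum(1 for r in rolls if r.race == lvl)
        assert rows[lvl]["count_with"] + rows[lvl]["count_without"] == total


def test_identical_columns_give_null_chi_square():
    rolls = ([_rollup(f"a{i}", race="Black", desc=True) for i in range(10)]
             + [_rollup(f"b{i}", race="White", desc=True) for i in range(10)]
             + [_rollup(f"c{i}", race="Black", desc=False) for i in range(10)]
             + [_rollup(f"d{i}", race="White", desc=False) for i in range(10)])
    t = prevalence_table(rolls, axes=("race",))
    assert t.p_values["race"] == pytest.approx(1.0)


def test_chi_square_matches_textbook_formula():
    a, b, c, d = 10, 20, 30, 40
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat, _ = chi_square([[a, b], [c, d]])
    assert stat == pytest.approx(expected)


# ----------------------------------------------------------------- odds ratio

def test_cross_product_odds_ratio():
    assert two_by_two_or(20, 80, 10, 90) == pytest.approx(2.25)


def _binary_cohort(n_exp_with, n_exp_without, n_unexp_with, n_unexp_without):
    rolls = []
    i = 0
    for race, desc, count in (("Black", True, n_exp_with),
                              ("Black", False, n_exp_without),
                              ("White", True, n_unexp_with),
                              ("White", False, n_unexp_without)):
        for _ in range(count):
            rolls.append(_rollup(f"p{i}", race=race, desc=desc))
            i += 1
    return rolls


def test_unadjusted_or_equals_closed_form():
    """The single-covariate logistic fit reproduces ad/bc to 1e-6."""
    rolls = _binary_cohort(20, 80, 10, 90)
    (res,) = odds_ratios(rolls, covariates=("race",))
    assert res.level == "Black" and res.reference == "White"
    assert res.or_unadjusted == pytest.approx(2.25, abs=1e-6)
    assert res.or_adjusted == pytest.approx(2.25, abs=1e-6)


def test_null_covariate_or_near_one():
    rng = np.random.default_rng(3)
    rolls = []
    for i in range(20000):
        race = "Black" if rng.random() < 0.5 else "White"
        rolls.append(_rollup(f"p{i}", race=race, desc=bool(rng.random() < 0.1)))
    (res,) = odds_ratios(rolls, covariates=("race",))
    assert 0.85 < res.or_unadjusted < 1.18


def test_separation_flagged_non_estimable():
    rolls = ([_rollup(f"a{i}", race="Black", desc=True) for i in range(5)]
             + [_rollup(f"b{i}", race="White", desc=True) for i in range(3)]
             + [_rollup(f"c{i}", race="White", desc=False) for i in range(3)]
             + [_rollup(f"d{i}", race="Other", desc=False) for i in range(4)])
    results = {r.level: r for r in odds_ratios(rolls, covariates=("race",))}
    assert not results["Black"].estimable  # all-with stratum
    assert not results["Other"].estimable  # all-without stratum


def test_adjusted_matches_unadjusted_without_confounding():
    """With independent axes and null co-effects, adjustment moves the OR
    only within Monte-Carlo error."""
    rng = np.random.default_rng(12)
    rolls = []
    for i in range(8000):
        race = "Black" if rng.random() < 0.5 else "White"
        age = "18-29" if rng.random() < 0.5 else "30-44"
        p = 0.15 if race == "Black" else 0.08
        rolls.append(_rollup(f"p{i}", race=race, age=age,
                             desc=bool(rng.random() < p)))
    (black,) = [r for r in odds_ratios(rolls, covariates=("race", "age_group"),
                                       references={"race": "White",
                                                   "age_group": "30-44"})
                if r.axis == "race"]
    assert black.or_adjusted == pytest.approx(black.or_unadjusted, rel=0.05)
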