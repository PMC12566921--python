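"""Featurization, model training, metric panel, corpus scoring, audit."""
import numpy as np
import pytest
from scipy import sparse

from chartlex import (FeatureSpec, KeywordHit, ModelSpec, Sentence,
                      classify_corpus, error_audit, evaluate, featurize,
                      train_model, LABEL_NEGATIVE, LABEL_NOT_NEGATIVE)
from chartlex.errors import ConfigurationError, TrainingError


def _sent(i, text, kw=None):
    from chartlex import tokenize
    s = Sentence(sentence_id=f"s{i}", note_id=f"n{i}", position=0, text=text,
                 token_count=len(tokenize(text)))
    if kw:
        s.keyword_hits = [KeywordHit(token=kw, term=kw, start=text.lower().find(kw))]
    return s


# ----------------------------------------------------------------- featurize

def test_unigram_counts_match_hand_tabulation():
    sents = [_sent(0, "agitated patient agitated"),
             _sent(1, "calm patient"),
             _sent(2, "patient refused meds")]
    spec = FeatureSpec(representation="counts", ngram_range=(1, 1),
                       min_document_frequency=1)
    X, vocab, _ = featurize(sents, spec)
    dense = X.toarray()
    hand = {"agitated": [2, 0, 0], "calm": [0, 1, 0], "meds": [0, 0, 1],
            "patient": [1, 1, 1], "refused": [0, 0, 1]}
    assert vocab == sorted(hand)
    for j, term in enumerate(vocab):
        assert dense[:, j].tolist() == hand[term]


def test_identical_sentences_identical_rows():
    sents = [_sent(0, "patient was combative"), _sent(1, "patient was combative")]
    X, _, _ = featurize(sents, FeatureSpec(min_document_frequency=1))
    assert (X[0] != X[1]).nnz == 0


def test_vocabulary_fit_on_train_only():
    train = [_sent(0, "alpha beta"), _sent(1, "alpha gamma")]
    test = [_sent(2, "delta epsilon alpha")]
    X, vocab, fz = featurize(train, FeatureSpec(ngram_range=(1, 1),
                                                min_document_frequency=1))
    Xt = fz.transform(test)
    assert "delta" not in vocab
    assert Xt.sum() == 1  # only "alpha" survives


def test_empty_vocabulary_rejected():
    with pytest.raises(ConfigurationError):
        featurize([_sent(0, "one"), _sent(1, "two")],
                  FeatureSpec(min_document_frequency=5))


# ------------------------------------------------------------------ training

def _toy_problem(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    return sparse.csr_matrix(X), y


def test_separable_problem_reaches_high_training_auroc():
    X, y = _toy_problem()
    model = train_model(X, y, ModelSpec(seed=1))
    from sklearn.metrics import roc_auc_score
    assert roc_auc_score(y, model.scores(X)) >= 0.99


def test_l1_limit_zeroes_all_coefficients():
    X, y = _toy_problem()
    spec = ModelSpec(seed=0, search="grid",
                     search_space={"C": [1e-6], "l1_ratio": [1.0]})
    model = train_model(X, y, spec)
    assert np.allclose(model.estimator.coef_, 0.0)


def test_single_class_labels_rejected():
    X, _ = _toy_problem()
    with pytest.raises(TrainingError):
        train_model(X, np.zeros(X.shape[0], dtype=int), ModelSpec())


def test_bayesian_search_families_train_deterministically():
    X, y = _toy_problem(n=80)
    spec = ModelSpec(family="random_forest", seed=3, search_budget=6)
    m1 = train_model(X, y, spec)
    m2 = train_model(X, y, ModelSpec(family="random_forest", seed=3,
                                     search_budget=6))
    assert m1.best_params == m2.best_params
    assert np.allclose(m1.scores(X), m2.scores(X))


# ---------------------------------------------------------------- evaluation

def test_perfect_predictor_metric_identities():
    y = [0, 1, 0, 1, 1, 0]
    scores = [0.1, 0.9, 0.2, 0.8, 0.95, 0.05]
    rep = evaluate(y, scores, n_bootstrap=50, seed=0)
    for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1",
              "auroc", "auprc"):
        assert rep.metrics[m][0] == pytest.approx(1.0)


def test_always_positive_predictor_closed_forms():
    """Scoring everything positive at prevalence p gives specificity 0,
    PPV = accuracy = p and F1 = 2p/(1+p)."""
    p = 0.08
    y = [1] * 8 + [0] * 92
    rep = evaluate(y, [1.0] * 100, n_bootstrap=50, seed=0)
    assert rep.metrics["specificity"][0] == 0.0
    assert rep.metrics["ppv"][0] == pytest.approx(p)
    assert rep.metrics["accuracy"][0] == pytest.approx(p)
    assert rep.metrics["f1"][0] == pytest.approx(2 * p / (1 + p))
    assert rep.prevalence == pytest.approx(p)


def test_random_scores_auroc_near_half():
    """Mann-Whitney null: AUROC of random scores within 3 s.e. of 0.5."""
    rng = np.random.default_rng(17)
    n1 = n0 = 1000
    y = np.array([1] * n1 + [0] * n0)
    scores = rng.random(n1 + n0)
    rep = evaluate(y, scores, n_bootstrap=10, seed=0)
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(rep.metrics["auroc"][0] - 0.5) < 3 * se


def test_threshold_monotonicity():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 300)
    scores = rng.random(300)
    sens, spec = [], []
    for t in np.linspace(0.05, 0.95, 10):
        rep = evaluate(y, scores, threshold=t, n_bootstrap=5, seed=0)
        sens.append(rep.metrics["sensitivity"][0])
        spec.append(rep.metrics["specificity"][0])
    assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
    assert all(b >= a - 1e-12 for a, b in zip(spec, spec[1:]))


def test_single_class_truth_reports_rank_metrics_absent():
    rep = evaluate([1, 1, 1], [0.9, 0.8, 0.7], n_bootstrap=10, seed=0)
    assert rep.metrics["auroc"] is None
    assert rep.metrics["auprc"] is None
    assert rep.metrics["sensitivity"][0] == 1.0


def test_interval_orders_and_bounds():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 200)
    scores = np.clip(y * 0.5 + rng.normal(0.3, 0.25, 200), 0, 1)
    rep = evaluate(y, scores, n_bootstrap=300, seed=1)
    for v in rep.metrics.values():
        if v is not None:
            point, lo, hi = v
            assert lo - 1e-9 <= point <= hi + 1e-9
            assert 0.0 <= point <= 1.0


def test_bootstrap_interval_coverage():
    """Nominal 95% accuracy intervals cover the true accuracy in at least
    90% of 200 synthetic replicates."""
    true_acc = 0.8
    rng = np.random.default_rng(99)
    covered = 0
    for _ in range(200):
        y = rng.integers(0, 2, 150)
        correct = rng.random(150) < true_acc
        scores = np.where(correct, y, 1 - y).astype(float)
        rep = evaluate(y, scores, n_bootstrap=200, seed=int(rng.integers(2**31)))
        _, lo, hi = rep.metrics["accuracy"]
        covered += lo <= true_acc <= hi
    assert covered >= 0.90 * 200


# ------------------------------------------------------ corpus + error audit

def _fit_text_model(seed=0):
    pos = [_sent(i, f"patient was combative with staff number {i}", "combative")
           for i in range(30)]
    neg = [_sent(100 + i, f"patient is not combative today number {i}", "combative")
           for i in range(30)]
    sents = pos + neg
    y = np.array([1] * 30 + [0] * 30)
    X, _, fz = featurize(sents, FeatureSpec(min_document_frequency=1))
    model = train_model(X, y, ModelSpec(seed=seed))
    return model, fz, sents, y


def test_classify_corpus_empty_and_rescore_consistency():
    model, fz, sents, y = _fit_text_model()
    assert classify_corpus(model, fz, []) == []
    preds = classify_corpus(model, fz, sents)
    relabel = [p["label"] == LABEL_NEGATIVE for p in preds]
    direct = (model.scores(fz.transform(sents)) >= 0.5).tolist()
    assert relabel == direct
    assert all(0.0 <= p["score"] <= 1.0 for p in preds)


def test_classify_corpus_tokenless_sentence_defaults_negative():
    model, fz, _, _ = _fit_text_model()
    blank = Sentence(sentence_id="blank", note_id="n", position=0,
                     text="!!!", token_count=0)
    (pred,) = classify_corpus(model, fz, [blank])
    assert pred["label"] == LABEL_NOT_NEGATIVE
    assert pred["score"] == 0.0


def test_error_audit_groups_by_keyword():
    sents = [_sent(0, "patient was agitated", "agitated"),
             _sent(1, "patient calm today", None),
             _sent(2, "patient refused meds", "refused")]
    truth = {"s0": LABEL_NEGATIVE, "s1": LABEL_NOT_NEGATIVE,
             "s2": LABEL_NEGATIVE}
    perfect = dict(truth)
    audit = error_audit(perfect, truth, sents)
    assert audit["false_positives"] == [] and audit["false_negatives"] == []

    preds = {"s0": LABEL_NOT_NEGATIVE, "s1": LABEL_NEGATIVE,
             "s2": LABEL_NEGATIVE}
    audit = error_audit(preds, truth, sents)
    assert audit["false_negatives"] == ["s0"]
    assert audit["fn_by_keyword"][0] == ("agitated", 1)
    assert audit["false_positives"] == ["s1"]
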