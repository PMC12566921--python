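"""Sentence classification: featurization, elastic-net and baseline model
training with cross-validated hyperparameter search, the full metric panel
with bootstrap intervals, corpus scoring and error auditing.

The primary model is binary logistic regression with elastic-net
regularization (a weighted L1/L2 penalty), trained on annotated keyword
sentences to separate "contains a negative descriptor" from "does not".
Baselines: plain logistic regression, random forest, linear-kernel-free
SVM.  Hyperparameters are chosen by mean 5-fold cross-validated AUROC —
grid search for the linear models, a seeded Gaussian-process
expected-improvement search for the ensemble/kernel models.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import FeatureSpec, ModelSpec
from .errors import ConfigurationError, TrainingError
from .text import tokenize
from .types import LABEL_NEGATIVE, LABEL_NOT_NEGATIVE, Sentence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# featurization

class SentenceFeaturizer:
    """Bag-of-n-grams featurizer fit on training sentences only.

    The vocabulary is learned at fit time and frozen; transforming unseen
    sentences maps out-of-vocabulary n-grams to nothing, so there is no
    train/test leakage by construction.
    """

    def __init__(self, spec: Optional[FeatureSpec] = None):
        self.spec = spec or FeatureSpec()
        self.spec.validate()
        cls = TfidfVectorizer if self.spec.representation == "tfidf" else CountVectorizer
        kwargs = dict(
            tokenizer=tokenize, preprocessor=lambda x: x, lowercase=False,
            token_pattern=None, ngram_range=tuple(self.spec.ngram_range),
            min_df=self.spec.min_document_frequency,
        )
        if cls is CountVectorizer:
            kwargs["binary"] = self.spec.representation == "binary"
        self._vectorizer = cls(**kwargs)
        self.vocabulary_: Optional[List[str]] = None

    def _window_text(self, sentence: Sentence) -> str:
        if self.spec.keyword_window is None or not sentence.keyword_hits:
            return sentence.text
        tokens = tokenize(sentence.text)
        hit_tokens = {h.token for h in sentence.keyword_hits}
        keep = set()
        for i, t in enumerate(tokens):
            if t in hit_tokens:
                lo = max(0, i - self.spec.keyword_window)
                hi = min(len(tokens), i + self.spec.keyword_window + 1)
                keep.update(range(lo, hi))
        return " ".join(tokens[i] for i in sorted(keep))

    def fit_transform(self, sentences: Sequence[Sentence]) -> sparse.spmatrix:
        texts = [self._window_text(s) for s in sentences]
        try:
            X = self._vectorizer.fit_transform(texts)
        except ValueError as exc:
            raise ConfigurationError(f"empty vocabulary after pruning: {exc}") from exc
        self.vocabulary_ = self._vectorizer.get_feature_names_out().tolist()
        return X

    def transform(self, sentences: Sequence[Sentence]) -> sparse.spmatrix:
        if self.vocabulary_ is None:
            raise ConfigurationError("featurizer must be fit before transform")
        return self._vectorizer.transform(self._window_text(s) for s in sentences)


def featurize(sentences: Sequence[Sentence], spec: Optional[FeatureSpec] = None
              ) -> Tuple[sparse.spmatrix, List[str], SentenceFeaturizer]:
    """Fit a featurizer on ``sentences`` and return (matrix, vocabulary, featurizer)."""
    fz = SentenceFeaturizer(spec)
    X = fz.fit_transform(sentences)
    return X, fz.vocabulary_, fz


# ---------------------------------------------------------------------------
# model training

_GRIDS = {
    "elastic_net_logistic": {"C": [0.01, 0.1, 1.0, 10.0], "l1_ratio": [0.2, 0.5, 0.8]},
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
}

#: Bayesian-search bounds: name -> (low, high, scale) with log10 or linear.
_BAYES_SPACES = {
    "random_forest": {"n_estimators": (50, 400, "int"),
                      "max_depth": (2, 30, "int"),
                      "min_samples_leaf": (1, 10, "int")},
    "svm": {"C": (-2.0, 2.0, "log10"), "gamma": (-4.0, 0.0, "log10")},
}


@dataclass
class FittedModel:
    estimator: object
    spec: ModelSpec
    best_params: dict
    cv_score: float
    search_log: list = field(default_factory=list)

    def scores(self, X) -> np.ndarray:
        """P(negative descriptor) per row, in [0, 1]."""
        return self.estimator.predict_proba(X)[:, 1]


def _make_estimator(family: str, params: dict, seed: int):
    if family == "elastic_net_logistic":
        return LogisticRegression(solver="saga", max_iter=5000,
                                  random_state=seed, **params)
    if family == "logistic":
        return LogisticRegression(solver="lbfgs", l1_ratio=0.0,
                                  max_iter=5000, random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    raise ConfigurationError(f"unknown family {family!r}")


def _cv_auroc(family: str, params: dict, X, y, folds: int, seed: int) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, val_idx in cv.split(X, y):
        est = _make_estimator(family, params, seed)
        est.fit(X[train_idx], y[train_idx])
        val_scores = est.predict_proba(X[val_idx])[:, 1]
        scores.append(roc_auc_score(y[val_idx], val_scores))
    return float(np.mean(scores))


def _grid_candidates(grid: dict) -> List[dict]:
    keys = sorted(grid)
    combos = [{}]
    for k in keys:
        combos = [{**c, k: v} for c in combos for v in grid[k]]
    return combos


def _regularization_rank(family: str, params: dict) -> tuple:
    """Sort key preferring stronger regularization on CV-score ties."""
    if family in ("elastic_net_logistic", "logistic"):
        return (params.get("C", 1.0), -params.get("l1_ratio", 0.0))
    if family == "random_forest":
        return (params.get("max_depth", 0), -params.get("min_samples_leaf", 0))
    return (params.get("C", 1.0),)


def _decode_point(space: dict, point: np.ndarray) -> dict:
    params = {}
    for (name, (lo, hi, scale)), v in zip(sorted(space.items()), point):
        raw = lo + (hi - lo) * v
        if scale == "int":
            params[name] = int(round(raw))
        elif scale == "log10":
            params[name] = float(10.0 ** raw)
        else:
            params[name] = float(raw)
    return params


def _bayesian_search(family: str, space: dict, X, y, spec: ModelSpec):
    """Seeded GP expected-improvement search over the unit hypercube."""
    rng = np.random.default_rng(spec.seed)
    dim = len(space)
    n_init = min(5, spec.search_budget)
    tried, observed = [], []
    points = rng.random((n_init, dim))
    for p in points:
        params = _decode_point(space, p)
        tried.append((p, params))
        observed.append(_cv_auroc(family, params, X, y, spec.cv_folds, spec.seed))
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), alpha=1e-4,
                                  normalize_y=True, random_state=spec.seed)
    for _ in range(spec.search_budget - n_init):
        gp.fit(np.array([t[0] for t in tried]), np.array(observed))
        cand = rng.random((256, dim))
        mu, sd = gp.predict(cand, return_std=True)
        best = max(observed)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / np.where(sd > 0, sd, 1.0)
            from scipy.stats import norm
            ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            ei[sd == 0] = 0.0
        p = cand[int(np.argmax(ei))]
        params = _decode_point(space, p)
        tried.append((p, params))
        observed.append(_cv_auroc(family, params, X, y, spec.cv_folds, spec.seed))
    order = sorted(range(len(tried)),
                   key=lambda i: (-observed[i],
                                  _regularization_rank(family, tried[i][1])))
    i = order[0]
    return tried[i][1], observed[i], [(t[1], o) for t, o in zip(tried, observed)]


def train_model(X, y, spec: Optional[ModelSpec] = None) -> FittedModel:
    """Fit one classifier family with cross-validated hyperparameter search.

    Model selection maximizes mean CV AUROC; exact ties break toward
    stronger regularization.  The winning configuration is refit on all of
    ``(X, y)``.
    """
    spec = spec or ModelSpec()
    spec.validate()
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training labels contain a single class")
    if int((y == 1).sum()) < spec.cv_folds:
        raise TrainingError("need at least cv_folds positive examples")

    use_bayes = (spec.search == "bayesian"
                 or (spec.search == "auto" and spec.family in _BAYES_SPACES))
    if use_bayes:
        space = spec.search_space or _BAYES_SPACES.get(spec.family)
        if space is None:
            raise ConfigurationError(f"no Bayesian space for {spec.family}")
        best_params, best_score, log = _bayesian_search(spec.family, space, X, y, spec)
    else:
        grid = spec.search_space or _GRIDS.get(spec.family)
        if grid is None:
            raise ConfigurationError(f"no grid for {spec.family}")
        log = []
        scored = []
        for params in _grid_candidates(grid):
            score = _cv_auroc(spec.family, params, X, y, spec.cv_folds, spec.seed)
            scored.append((params, score))
            log.append((params, score))
        scored.sort(key=lambda ps: (-round(ps[1], 12),
                                    _regularization_rank(spec.family, ps[0])))
        best_params, best_score = scored[0]

    est = _make_estimator(spec.family, best_params, spec.seed)
    est.fit(X, y)
    return FittedModel(estimator=est, spec=spec, best_params=best_params,
                       cv_score=best_score, search_log=log)


# ---------------------------------------------------------------------------
# evaluation

_METRICS = ("auroc", "sensitivity", "specificity", "ppv", "npv",
            "f1", "accuracy", "auprc")


@dataclass
class MetricsReport:
    """Point estimates with 95% bootstrap intervals for the full panel."""

    metrics: Dict[str, tuple]  # name -> (point, lo, hi); rank metrics may be None
    threshold: float
    n: int
    prevalence: float

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold, "n": self.n, "prevalence": self.prevalence,
            "metrics": {k: (None if v is None else
                            {"point": v[0], "ci95": [v[1], v[2]]})
                        for k, v in self.metrics.items()},
        }


def _panel(y: np.ndarray, scores: np.ndarray, threshold: float) -> Dict[str, float]:
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    div = lambda a, b: a / b if b else np.nan
    out = {
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
        "accuracy": div(tp + tn, len(y)),
        "f1": div(2 * tp, 2 * tp + fp + fn),
    }
    if len(np.unique(y)) > 1:
        out["auroc"] = float(roc_auc_score(y, scores))
        out["auprc"] = float(average_precision_score(y, scores))
    else:
        out["auroc"] = np.nan
        out["auprc"] = np.nan
    return out


def evaluate(y_true: Sequence[int], scores: Sequence[float],
             threshold: float = 0.5, n_bootstrap: int = 1000,
             seed: int = 0) -> MetricsReport:
    """Full metric panel at ``threshold`` with 95% bootstrap intervals.

    Intervals are percentile bootstrap over test items (``n_bootstrap``
    resamples, seeded).  With a single-class truth vector the rank metrics
    (AUROC/AUPRC) are reported as absent with a warning.
    """
    y = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(y) == 0:
        raise ConfigurationError("cannot evaluate on an empty test set")
    single_class = len(np.unique(y)) < 2
    if single_class:
        logger.warning("single-class test labels: AUROC/AUPRC undefined")
    point = _panel(y, scores, threshold)
    rng = np.random.default_rng(seed)
    boot = {m: [] for m in _METRICS}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(y), len(y))
        rep = _panel(y[idx], scores[idx], threshold)
        for m in _METRICS:
            boot[m].append(rep[m])
    metrics = {}
    for m in _METRICS:
        if np.isnan(point[m]):
            metrics[m] = None
            continue
        arr = np.asarray(boot[m], dtype=float)
        lo, hi = np.nanpercentile(arr, [2.5, 97.5])
        metrics[m] = (float(point[m]), float(lo), float(hi))
    return MetricsReport(metrics=metrics, threshold=threshold, n=len(y),
                         prevalence=float(y.mean()))


def compare_families(X_train, y_train, X_test, y_test,
                     families: Sequence[str] = ModelSpec.FAMILIES,
                     seed: int = 0, n_bootstrap: int = 500) -> Dict[str, dict]:
    """Train every family on the same split; one report column per family
    for both train and test data."""
    table = {}
    for family in families:
        spec = ModelSpec(family=family, search="auto", seed=seed)
        model = train_model(X_train, y_train, spec)
        table[family] = {
            "best_params": model.best_params,
            "train": evaluate(y_train, model.scores(X_train),
                              n_bootstrap=n_bootstrap, seed=seed).as_dict(),
            "test": evaluate(y_test, model.scores(X_test),
                             n_bootstrap=n_bootstrap, seed=seed).as_dict(),
        }
    return table


# ---------------------------------------------------------------------------
# corpus classification and auditing

def classify_corpus(model: FittedModel, featurizer: SentenceFeaturizer,
                    sentences: Sequence[Sentence],
                    threshold: float = 0.5) -> List[dict]:
    """Score unlabeled keyword sentences with the trained model.

    Each row gets a probability in [0, 1] and a hard label.  A sentence
    with no tokens cannot be featurized and is labeled not-negative with a
    warning.
    """
    if not sentences:
        return []
    results = []
    featurizable = [s for s in sentences if tokenize(s.text)]
    skipped = [s for s in sentences if not tokenize(s.text)]
    for s in skipped:
        logger.warning("sentence %s has no tokens; labeling not-negative", s.sentence_id)
        results.append({"sentence_id": s.sentence_id, "score": 0.0,
                        "label": LABEL_NOT_NEGATIVE})
    if featurizable:
        X = featurizer.transform(featurizable)
        scores = model.scores(X)
        for s, sc in zip(featurizable, scores):
            results.append({
                "sentence_id": s.sentence_id, "score": float(sc),
                "label": LABEL_NEGATIVE if sc >= threshold else LABEL_NOT_NEGATIVE,
            })
    order = {s.sentence_id: i for i, s in enumerate(sentences)}
    results.sort(key=lambda r: order[r["sentence_id"]])
    return results


def error_audit(predictions: Dict[str, str], truth: Dict[str, str],
                sentences: Sequence[Sentence]) -> dict:
    """False positives and false negatives grouped by matched keyword.

    ``predictions`` and ``truth`` map sentence id to a label; truth labels
    other than negative-descriptor count as negative-class.  Returns FP/FN
    sentence lists plus per-keyword counts, with the FN ranking sorted by
    frequency.
    """
    by_id = {s.sentence_id: s for s in sentences}
    fps, fns = [], []
    fp_by_kw, fn_by_kw = {}, {}
    for sid, pred in predictions.items():
        true = truth.get(sid)
        if true is None or sid not in by_id:
            continue
        pred_pos = pred == LABEL_NEGATIVE
        true_pos = true == LABEL_NEGATIVE
        if pred_pos == true_pos:
            continue
        s = by_id[sid]
        kw = s.keyword_hits[0].term if s.keyword_hits else "(none)"
        if pred_pos:
            fps.append(sid)
            fp_by_kw[kw] = fp_by_kw.get(kw, 0) + 1
        else:
            fns.append(sid)
            fn_by_kw[kw] = fn_by_kw.get(kw, 0) + 1
    rank = lambda d: sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))
    return {"false_positives": fps, "false_negatives": fns,
            "fp_by_keyword": rank(fp_by_kw), "fn_by_keyword": rank(fn_by_kw)}
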