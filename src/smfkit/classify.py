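"""Classifier bank, repeated stratified cross-validation and AUC inference.

Five models are benchmarked on fingerprint matrices: L2-regularized logistic
regression ("ridge", inverse strength 1/0.140), AdaBoost over decision trees
(60 estimators, learn rate 1.0), k-nearest neighbors (k=5, uniform,
Euclidean), Gaussian naive Bayes, and the fingerprint neural network of
:mod:`smfkit.nn`.  Evaluation follows repeated stratified 10-fold
cross-validation (10 repeats by default) with feature standardization fit on
the training folds only, and reports AUC with DeLong 95% confidence
intervals, the DeLong paired test, and threshold metrics (accuracy, F1,
MCC, recall/sensitivity, precision, specificity) at probability 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .containers import FeatureMatrix
from .nn import NNArchitecture, NeuralNetClassifier

__all__ = [
    "ModelSpec", "MetricSet", "CVReport",
    "crossvalidate", "fit_model", "confusion_metrics",
    "auc_delong", "delong_test", "repeat_stability",
]

MODEL_NAMES = ("ridge", "adaboost", "knn", "naive_bayes", "nn")


@dataclass
class ModelSpec:
    """A named model with its (printed-default) hyperparameters."""

    name: str = "nn"
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    DEFAULTS = {
        "ridge": {"alpha": 0.140},
        "adaboost": {"n_estimators": 60, "learning_rate": 1.0,
                     "algorithm": "SAMME.R"},
        "knn": {"n_neighbors": 5, "weights": "uniform", "metric": "euclidean"},
        "naive_bayes": {},
        "nn": {"batch_size": 32, "epochs": 200, "drop_rate": 0.25},
    }

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        merged = dict(self.DEFAULTS[self.name])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


def fit_model(spec: ModelSpec, x: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one model on standardized features; returns a scorer with
    ``decision_scores(X) -> P(class 1)``."""
    hp = spec.hyperparameters
    if spec.name == "ridge":
        est = LogisticRegression(C=1.0 / hp["alpha"], max_iter=2000)
    elif spec.name == "adaboost":
        # base estimator is a full decision tree (no depth cap), not a stump
        est = AdaBoostClassifier(estimator=DecisionTreeClassifier(random_state=seed),
                                 n_estimators=hp["n_estimators"],
                                 learning_rate=hp["learning_rate"],
                                 random_state=seed)
    elif spec.name == "knn":
        est = KNeighborsClassifier(n_neighbors=hp["n_neighbors"],
                                   weights=hp["weights"], metric=hp["metric"])
    elif spec.name == "naive_bayes":
        est = GaussianNB()
    else:
        arch = NNArchitecture(batch_size=hp["batch_size"], epochs=hp["epochs"],
                              drop_rate=hp["drop_rate"], seed=seed,
                              input_length=max(144, x.shape[1]))
        return NeuralNetClassifier(arch).fit(x, y)
    est.fit(x, y)

    class _SkScorer:
        def __init__(self, model):
            self.model = model

        def decision_scores(self, xx):
            return self.model.predict_proba(xx)[:, 1]

    return _SkScorer(est)


@dataclass
class MetricSet:
    """Threshold metrics from one confusion matrix plus AUC with 95% CI.

    Metrics with a zero denominator are reported as NaN (undefined), never
    silently as 0.
    """

    auc: float = math.nan
    auc_ci: tuple[float, float] = (math.nan, math.nan)
    accuracy: float = math.nan
    f1: float = math.nan
    recall: float = math.nan
    precision: float = math.nan
    specificity: float = math.nan
    mcc: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {"auc": self.auc, "auc_ci_low": self.auc_ci[0],
                "auc_ci_high": self.auc_ci[1], "accuracy": self.accuracy,
                "f1": self.f1, "recall": self.recall,
                "precision": self.precision, "specificity": self.specificity,
                "mcc": self.mcc}


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> MetricSet:
    """Threshold-level metric set from confusion-matrix counts."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    acc = (tp + tn) / total
    rec = ratio(tp, tp + fn)
    prec = ratio(tp, tp + fp)
    spec = ratio(tn, tn + fp)
    f1 = (2 * prec * rec / (prec + rec)
          if prec == prec and rec == rec and (prec + rec) > 0 else math.nan)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else math.nan
    return MetricSet(accuracy=acc, f1=f1, recall=rec, precision=prec,
                     specificity=spec, mcc=mcc)


# ---------------------------------------------------------------------------
# DeLong AUC machinery

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def auc_delong(scores, labels) -> tuple[float, float, tuple[float, float]]:
    """AUC (Mann-Whitney, ties counted 1/2), DeLong variance and 95% CI."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(scores, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), float(var), ci


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided p-value for the difference of two correlated AUCs.

    Both score vectors must be over the same samples (paired design).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("paired scores require equal lengths")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    var_a = np.var(v10_a, ddof=1) / m + np.var(v01_a, ddof=1) / n
    var_b = np.var(v10_b, ddof=1) / m + np.var(v01_b, ddof=1) / n
    cov = (np.cov(v10_a, v10_b, ddof=1)[0, 1] / m +
           np.cov(v01_a, v01_b, ddof=1)[0, 1] / n)
    var_diff = var_a + var_b - 2 * cov
    if var_diff <= 0:
        return 1.0
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# cross-validation

def _encode_labels(labels: np.ndarray) -> tuple[np.ndarray, str]:
    uniq = sorted(map(str, set(labels)))
    if len(uniq) != 2:
        raise ValueError(f"two classes required, got {uniq}")
    for cand in ("case", "MMD"):
        if cand in uniq:
            pos = cand
            break
    else:
        pos = uniq[1]
    y = np.array([1 if str(v) == pos else 0 for v in labels])
    return y, pos


@dataclass
class CVReport:
    """Out-of-fold scores and derived metrics of one repeated CV run."""

    out_of_fold_scores: np.ndarray  # repeats x samples
    fold_assignment: np.ndarray  # repeats x samples
    y: np.ndarray  # 0/1, positive = case
    model: ModelSpec
    seed: int = 0
    positive_label: str = "case"

    def pooled_scores(self) -> np.ndarray:
        """Mean out-of-fold score per sample across repeats."""
        return self.out_of_fold_scores.mean(axis=0)

    def auc_per_repeat(self) -> np.ndarray:
        return np.array([auc_delong(s, self.y)[0] for s in self.out_of_fold_scores])

    def metrics(self, threshold: float = 0.5, pooled: bool = True) -> MetricSet:
        scores = self.pooled_scores() if pooled else self.out_of_fold_scores[0]
        auc, _, ci = auc_delong(scores, self.y)
        pred = (scores >= threshold).astype(int)
        tp = int(np.sum((pred == 1) & (self.y == 1)))
        fp = int(np.sum((pred == 1) & (self.y == 0)))
        fn = int(np.sum((pred == 0) & (self.y == 1)))
        tn = int(np.sum((pred == 0) & (self.y == 0)))
        ms = confusion_metrics(tp, fp, fn, tn)
        ms.auc, ms.auc_ci = auc, ci
        return ms


def crossvalidate(matrix: FeatureMatrix, model: ModelSpec | str,
                  k: int = 10, repeats: int = 10, seed: int = 0) -> CVReport:
    """Repeated stratified k-fold CV with leakage-safe standardization.

    Per repeat the samples are split into k stratified folds; per fold a
    StandardScaler and the model are fit on the training folds only and the
    held-out fold is scored.  Every sample is scored exactly once per
    repeat.  Deterministic given ``seed``.
    """
    if isinstance(model, str):
        model = ModelSpec(model)
    if matrix.labels is None:
        raise ValueError("feature matrix has no group labels")
    y, pos = _encode_labels(matrix.labels)
    counts = np.bincount(y)
    if counts.min() < k and k < matrix.n_samples:
        raise ValueError(f"k={k} exceeds the smaller class size {counts.min()}")
    x = matrix.values

    n = len(y)
    scores = np.zeros((repeats, n))
    folds = np.zeros((repeats, n), dtype=int)
    for r in range(repeats):
        if k >= n:  # leave-one-out degenerate mode
            splits = [(np.setdiff1d(np.arange(n), [i]), np.array([i]))
                      for i in range(n)]
        else:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
            splits = list(skf.split(x, y))
        for f, (train, test) in enumerate(splits):
            scaler = StandardScaler().fit(x[train])
            xt, xv = scaler.transform(x[train]), scaler.transform(x[test])
            scorer = fit_model(model, xt, y[train], seed=seed + 1000 * r + f)
            scores[r, test] = scorer.decision_scores(xv)
            folds[r, test] = f
    return CVReport(scores, folds, y, model, seed=seed, positive_label=pos)


def repeat_stability(matrix: FeatureMatrix, model: ModelSpec | str,
                     n_runs: int = 10, k: int = 10, seed: int = 0) -> dict:
    """AUC over n_runs independent CV seeds: per-run values, mean and sd."""
    aucs = []
    for i in range(n_runs):
        rep = crossvalidate(matrix, model, k=k, repeats=1, seed=seed + 7919 * i)
        aucs.append(float(rep.auc_per_repeat()[0]))
    aucs = np.array(aucs)
    return {"auc_runs": aucs.tolist(), "mean": float(aucs.mean()),
            "sd": float(aucs.std(ddof=1)) if n_runs > 1 else math.nan}
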