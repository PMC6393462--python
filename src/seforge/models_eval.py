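"""Classifier benchmark: stratified cross-validation and evaluation metrics.

The model panel covers the standard supervised learners used for SE/TE
classification: a random forest (20 trees — chosen by out-of-bag error in
this problem family), SVMs with linear / RBF / polynomial kernels (C = 1),
k-nearest neighbours, AdaBoost on decision stumps, Gaussian naive Bayes and
a single decision tree.

Metrics: precision, recall, F1 on hard predictions; ROC AUC via the
Mann-Whitney rank statistic (ties count 1/2 — identical to trapezoidal
integration of the ROC curve); PR AUC via step-wise interpolation (average
precision).  Pooled metrics concatenate held-out scores across folds and
are the headline numbers; per-fold values are retained.

``auc_permutation_test`` compares two score vectors on the same rows by
randomly swapping paired scores, and ``wilcoxon_rank_sum`` is the two-sided
Mann-Whitney U test with exact enumeration for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from seforge.genomics_io import FeatureMatrix, ValidationError

MODEL_NAMES = (
    "random_forest",
    "svm_linear",
    "svm_rbf",
    "svm_poly",
    "knn",
    "adaboost",
    "naive_bayes",
    "decision_tree",
)

#: the six-model benchmark panel (one SVM kernel, the linear one)
DEFAULT_PANEL = (
    "random_forest",
    "svm_linear",
    "knn",
    "adaboost",
    "naive_bayes",
    "decision_tree",
)


@dataclass
class ModelSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.hyperparameters.get("trees", 1) < 1:
            raise ValueError("trees must be >= 1")
        if self.hyperparameters.get("C", 1.0) <= 0:
            raise ValueError("C must be > 0")

    def build(self, seed: int):
        hp = self.hyperparameters
        if self.name == "random_forest":
            return RandomForestClassifier(
                n_estimators=hp.get("trees", 20), random_state=seed, n_jobs=1
            )
        if self.name == "svm_linear":
            return SVC(kernel="linear", C=hp.get("C", 1.0), random_state=seed)
        if self.name == "svm_rbf":
            return SVC(kernel="rbf", C=hp.get("C", 1.0), random_state=seed)
        if self.name == "svm_poly":
            return SVC(kernel="poly", C=hp.get("C", 1.0), random_state=seed)
        if self.name == "knn":
            return KNeighborsClassifier(n_neighbors=hp.get("k", 5))
        if self.name == "adaboost":
            return AdaBoostClassifier(
                n_estimators=hp.get("n_estimators", 50), random_state=seed
            )
        if self.name == "naive_bayes":
            return GaussianNB()
        return DecisionTreeClassifier(random_state=seed)


@dataclass
class ModelResult:
    precision: float
    recall: float
    f1: float
    roc_auc: float
    pr_auc: float
    fold_roc_auc: list[float]
    fold_pr_auc: list[float]
    scores: np.ndarray
    predictions: np.ndarray
    error: str | None = None


@dataclass
class EvalReport:
    results: dict[str, ModelResult]
    fold_assignment: np.ndarray
    n_folds: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, r in self.results.items():
            rows[name] = {
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
                "roc_auc": r.roc_auc,
                "pr_auc": r.pr_auc,
                "fold_roc_auc_mean": float(np.mean(r.fold_roc_auc)),
                "fold_roc_auc_sd": float(np.std(r.fold_roc_auc)),
            }
        return pd.DataFrame(rows).T


def stratified_folds(labels, n_folds: int = 10, seed: int = 1) -> np.ndarray:
    """Per class, shuffle rows (seeded) and deal round-robin into folds."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValidationError(
                f"class {cls} has {len(idx)} rows, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def roc_auc(scores, labels) -> float:
    """ROC AUC via the rank statistic; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc requires both classes")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    pos_rank_sum = ranks[y == 1].sum()
    u = pos_rank_sum - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise interpolation."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0 or np.sum(y == 0) == 0:
        raise ValidationError("pr_auc requires both classes")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last point of each tied-score block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # step-wise: area = sum over thresholds of (delta recall) * precision
    prev_recall = 0.0
    area = 0.0
    for p, r in zip(precision, recall):
        area += (r - prev_recall) * p
        prev_recall = r
    return float(area)


def prf1(predictions, labels) -> tuple[float, float, float]:
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def _model_scores(model, X) -> np.ndarray:
    """Continuous scores for ranking; decision functions are min-max
    rescaled to [0, 1] per fold."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    s = model.decision_function(X)
    lo, hi = s.min(), s.max()
    return (s - lo) / (hi - lo) if hi > lo else np.full_like(s, 0.5)


def cross_validate(
    m: FeatureMatrix,
    models: list[ModelSpec] | None = None,
    n_folds: int = 10,
    seed: int = 1,
) -> EvalReport:
    """Stratified k-fold CV with identical folds shared across models.

    Pooled metrics are computed on the concatenated held-out scores; a model
    whose fit fails is recorded with an error and the run continues.
    """
    if m.labels is None:
        raise ValidationError("cross_validate requires labels")
    if models is None:
        models = [ModelSpec(name) for name in DEFAULT_PANEL]
    X = m.values.to_numpy(dtype=float)
    y = np.asarray(m.labels)
    folds = stratified_folds(y, n_folds=n_folds, seed=seed)
    results: dict[str, ModelResult] = {}
    for spec in models:
        scores = np.empty(len(y))
        preds = np.empty(len(y), dtype=int)
        fold_rocs, fold_prs = [], []
        try:
            for f in range(n_folds):
                test = folds == f
                model = spec.build(seed)
                model.fit(X[~test], y[~test])
                scores[test] = _model_scores(model, X[test])
                preds[test] = model.predict(X[test])
                fold_rocs.append(roc_auc(scores[test], y[test]))
                fold_prs.append(pr_auc(scores[test], y[test]))
        except Exception as exc:  # record per-model failure, keep going
            results[spec.name] = ModelResult(
                np.nan, np.nan, np.nan, np.nan, np.nan, [], [],
                np.array([]), np.array([]), error=str(exc),
            )
            continue
        precision, recall, f1 = prf1(preds, y)
        results[spec.name] = ModelResult(
            precision=precision,
            recall=recall,
            f1=f1,
            roc_auc=roc_auc(scores, y),
            pr_auc=pr_auc(scores, y),
            fold_roc_auc=fold_rocs,
            fold_pr_auc=fold_prs,
            scores=scores,
            predictions=preds,
        )
    return EvalReport(results=results, fold_assignment=folds, n_folds=n_folds, seed=seed)


def auc_permutation_test(
    scores_a, scores_b, labels, n_perm: int = 1000, seed: int = 1
) -> float:
    """Paired permutation test for |AUC(a) - AUC(b)|.

    Each permutation swaps a_i <-> b_i per row with probability 1/2;
    p = (1 + #{d_perm >= d_obs}) / (1 + n_perm).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if len(a) != len(b) or len(a) != len(y):
        raise ValidationError("scores_a, scores_b and labels must align")
    d_obs = abs(roc_auc(a, y) - roc_auc(b, y))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(len(a)) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        if abs(roc_auc(pa, y) - roc_auc(pb, y)) >= d_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all C(n_x + n_y, n_x) arrangements when the pooled
    size is <= 12; otherwise the normal approximation with tie correction.
    Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = ranks[:nx].sum() - nx * (nx + 1) / 2
    if nx + ny <= 12:
        # exact two-sided p by enumerating all group assignments
        n = nx + ny
        mean_u = nx * ny / 2
        d_obs = abs(u_x - mean_u)
        count = 0
        total = comb(n, nx)
        for combo in combinations(range(n), nx):
            u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
            if abs(u - mean_u) >= d_obs - 1e-12:
                count += 1
        return float(u_x), count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u_x), float(res.pvalue)
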