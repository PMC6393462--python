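"""Feature relevance ranking.

Two complementary importance measures over a labelled feature matrix:

* ``shadow_rank`` — a Boruta-style shadow-feature procedure.  Each
  iteration appends a shuffled copy (shadow) of every real feature, fits a
  random forest, and records impurity-based importances for real and shadow
  features from the same fitted model.  A real feature scores a "hit" when
  its importance exceeds the maximum shadow importance that iteration.
  After all iterations a two-sided binomial test against Binomial(n, 0.5)
  classifies features as Confirmed (significantly many hits), Rejected
  (significantly few), or Tentative.  This is the single-pass variant: no
  features are removed between iterations.

* ``oob_importance`` — out-of-bag permutation importance from a hand-built
  bagged forest: per tree, accuracy on the bootstrap-excluded rows is
  compared with accuracy after permuting one feature within those rows; the
  importance is the mean accuracy decrease across trees.

``importance_correlation`` quantifies agreement between the two score
vectors (Pearson r, Fisher-z 95% CI, t-test p), and
``feature_correlation_matrix`` gives the pairwise feature correlation
structure of a matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from seforge.genomics_io import FeatureMatrix, ValidationError

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"


@dataclass
class FeatureImportanceReport:
    feature_names: list[str]
    importances: np.ndarray  # iterations x features
    shadow_max: np.ndarray  # per-iteration max shadow importance
    hits: np.ndarray  # per-feature hit counts
    status: dict[str, str]
    iterations: int
    alpha: float

    def median_importance(self) -> pd.Series:
        return pd.Series(
            np.median(self.importances, axis=0), index=self.feature_names
        ).sort_values(ascending=False)

    def confirmed(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == CONFIRMED]

    def rejected(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == REJECTED]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "median_importance": np.median(self.importances, axis=0),
                "hits": self.hits,
                "status": [self.status[f] for f in self.feature_names],
            },
            index=self.feature_names,
        )


def _check_labelled(m: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    if m.labels is None:
        raise ValidationError("a labelled matrix is required")
    y = np.asarray(m.labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    return m.values.to_numpy(dtype=float), y


def shadow_rank(
    m: FeatureMatrix,
    iterations: int = 50,
    alpha: float = 0.01,
    n_trees: int = 20,
    seed: int = 1,
) -> FeatureImportanceReport:
    X, y = _check_labelled(m)
    if X.shape[1] < 2:
        raise ValidationError("shadow_rank requires at least 2 features")
    rng = np.random.default_rng(seed)
    n_features = X.shape[1]
    importances = np.empty((iterations, n_features))
    shadow_max = np.empty(iterations)
    hits = np.zeros(n_features, dtype=int)
    for it in range(iterations):
        shadows = X.copy()
        for j in range(n_features):
            shadows[:, j] = rng.permutation(shadows[:, j])
        augmented = np.hstack([X, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(augmented, y)
        imp = forest.feature_importances_
        real, shadow = imp[:n_features], imp[n_features:]
        importances[it] = real
        shadow_max[it] = shadow.max()
        hits += real > shadow_max[it]
    status = {}
    for j, name in enumerate(m.feature_names):
        p = stats.binomtest(int(hits[j]), iterations, 0.5).pvalue
        if p < alpha:
            status[name] = CONFIRMED if hits[j] > iterations / 2 else REJECTED
        else:
            status[name] = TENTATIVE
    return FeatureImportanceReport(
        feature_names=m.feature_names,
        importances=importances,
        shadow_max=shadow_max,
        hits=hits,
        status=status,
        iterations=iterations,
        alpha=alpha,
    )


def oob_importance(
    m: FeatureMatrix, n_trees: int = 20, seed: int = 1
) -> pd.Series:
    """Mean out-of-bag accuracy decrease per feature across a bagged forest."""
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    X, y = _check_labelled(m)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros((n_trees, p))
    counts = np.zeros(p)
    max_features = max(1, int(np.sqrt(p)))  # forest-style feature subsampling
    for t in range(n_trees):
        boot = rng.integers(n, size=n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        if not oob_mask.any():
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        X_oob, y_oob = X[oob_mask], y[oob_mask]
        base_acc = np.mean(tree.predict(X_oob) == y_oob)
        for j in range(p):
            X_perm = X_oob.copy()
            X_perm[:, j] = rng.permutation(X_perm[:, j])
            drops[t, j] = base_acc - np.mean(tree.predict(X_perm) == y_oob)
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        scores = drops.sum(axis=0) / np.maximum(counts, 1)
    return pd.Series(scores, index=m.feature_names)


def importance_correlation(a, b) -> tuple[float, float, float, float]:
    """Pearson r between two score vectors with Fisher-z 95% CI and t-test p.

    Returns (r, ci_low, ci_high, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValidationError("score vectors must have equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("zero variance in a score vector")
    r, p = stats.pearsonr(a, b)
    n = len(a)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    ci_low = float(np.tanh(z - 1.959963984540054 * se))
    ci_high = float(np.tanh(z + 1.959963984540054 * se))
    return float(r), ci_low, ci_high, float(p)


def feature_correlation_matrix(
    m: FeatureMatrix, row_subset: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric Pearson correlation of features; constant columns give NaN
    off-diagonals (with a warning) and 1 on the diagonal."""
    df = m.values if row_subset is None else m.values.loc[row_subset]
    if len(df) < 2:
        raise ValidationError("need at least 2 rows for correlation")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant feature(s) {constant}: correlations undefined, recorded as NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
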