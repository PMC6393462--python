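"""Class balancing for the SE/TE training matrix.

SE constituents are heavily outnumbered by TE constituents (hundreds vs
thousands), so models trained on raw data over-predict the majority class.
Three strategies are provided: SMOTE oversampling of the minority class,
random under-sampling of the majority class, and the hybrid that first
grows the minority with SMOTE and then under-samples the majority to match.

The SMOTE variant follows Weka semantics: the oversampling percentage is a
multiple of 100 (whole passes over the minority set), synthetic points are
interpolated between each minority row and one of its k nearest minority
neighbours (Euclidean, on raw features), cycling through the rows in order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from seforge.genomics_io import FeatureMatrix, ValidationError


@dataclass
class SamplingConfig:
    smote_percentage: int = 500
    smote_k: int = 5
    seed: int = 1
    mode: str = "hybrid"

    def __post_init__(self) -> None:
        if self.smote_percentage < 0 or self.smote_percentage % 100 != 0:
            raise ValueError("smote_percentage must be a non-negative multiple of 100")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.mode not in ("under", "over", "hybrid"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")


def smote(minority: pd.DataFrame, cfg: SamplingConfig) -> pd.DataFrame:
    """Generate m * percentage/100 synthetic rows from the minority class.

    Rows are cycled in order; for each, one of its k nearest minority
    neighbours is drawn uniformly and a point x + u*(neighbour - x) with
    u ~ Uniform(0, 1) is emitted.  Neighbour ties break by row order.
    """
    m = len(minority)
    if m < 2:
        raise ValidationError("SMOTE requires at least 2 minority rows")
    k = min(cfg.smote_k, m - 1)
    n_syn = m * cfg.smote_percentage // 100
    X = minority.to_numpy(dtype=float)
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    # stable argsort => ties broken by row order
    neighbor_idx = np.argsort(dist, axis=1, kind="stable")[:, :k]
    rng = np.random.default_rng(cfg.seed)
    rows = np.empty((n_syn, X.shape[1]))
    for i in range(n_syn):
        src = i % m
        nb = neighbor_idx[src, rng.integers(k)]
        u = rng.random()
        rows[i] = X[src] + u * (X[nb] - X[src])
    index = [f"synthetic_{i}" for i in range(n_syn)]
    return pd.DataFrame(rows, index=index, columns=minority.columns)


def undersample(majority: pd.DataFrame, target_n: int, seed: int) -> pd.DataFrame:
    """Uniform sample without replacement of target_n majority rows."""
    if target_n > len(majority):
        raise ValidationError(
            f"cannot undersample to {target_n} from {len(majority)} rows"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(majority), size=target_n, replace=False)
    return majority.iloc[np.sort(idx)]


def hybrid_sample(m: FeatureMatrix, cfg: SamplingConfig | None = None) -> FeatureMatrix:
    """SMOTE the minority to m*(1 + pct/100) rows, under-sample the majority
    to the same size; the output is exactly 50/50 balanced.

    Synthetic rows are flagged with a ``synthetic_`` id prefix.
    """
    cfg = cfg if cfg is not None else SamplingConfig()
    if m.labels is None:
        raise ValidationError("hybrid_sample requires labels")
    labels = np.asarray(m.labels)
    pos = m.values[labels == 1]
    neg = m.values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be non-empty")
    minority, majority, min_label = (
        (pos, neg, 1) if len(pos) <= len(neg) else (neg, pos, 0)
    )
    target = len(minority) * (100 + cfg.smote_percentage) // 100
    if cfg.smote_percentage > 0:
        synthetic = smote(minority, cfg)
        minority_out = pd.concat([minority, synthetic])
    else:
        minority_out = minority
    majority_out = undersample(majority, len(minority_out), cfg.seed)
    assert len(minority_out) == target
    combined = pd.concat([minority_out, majority_out])
    out_labels = np.concatenate(
        [
            np.full(len(minority_out), min_label, dtype=int),
            np.full(len(majority_out), 1 - min_label, dtype=int),
        ]
    )
    return FeatureMatrix(combined, labels=out_labels)
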