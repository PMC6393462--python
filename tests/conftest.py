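import numpy as np
import pandas as pd
import pytest

from seforge.genomics_io import FeatureMatrix, GenomicInterval, ReadAlignmentSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_labelled_matrix():
    """500 rows, one planted feature (2 SD class shift), 10 noise, 1 constant."""
    gen = np.random.default_rng(1)
    n = 500
    X = gen.standard_normal((n, 11))
    y = gen.integers(0, 2, n)
    X[:, 0] += 2.0 * y
    df = pd.DataFrame(
        X,
        index=[f"r{i}" for i in range(n)],
        columns=["planted"] + [f"noise{i}" for i in range(10)],
    )
    df["const"] = 1.0
    return FeatureMatrix(df, labels=y)


def make_reads(intervals, total_mapped):
    return ReadAlignmentSet(
        [GenomicInterval(*iv) if isinstance(iv, tuple) else iv for iv in intervals],
        total_mapped,
    )
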