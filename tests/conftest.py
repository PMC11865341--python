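import numpy as np
import pytest
import scipy.sparse as sp

from spatzone.io import SpatialBinMatrix
from spatzone.scoring import ScoreVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """5 genes x 4 bins with equal per-bin totals (normalization-friendly)."""
    counts = np.array([
        [10, 10, 10, 10],
        [5, 5, 5, 5],
        [20, 20, 20, 20],
        [1, 1, 1, 1],
        [4, 4, 4, 4],
    ])
    return SpatialBinMatrix(
        genes=[f"g{i}" for i in range(5)],
        bin_ids=[f"b{i}" for i in range(4)],
        counts=sp.csr_matrix(counts),
        coords=np.array([[0, 0], [1, 0], [0, 1], [1, 1]]),
        bin_size=20,
    )


def make_scores(values, coords=None):
    values = np.asarray(values, dtype=float)
    return ScoreVector(
        name="test", bin_ids=[f"b{i}" for i in range(len(values))],
        values=values, n_expression_bins=0, n_controls_per_gene=0, seed=None)
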