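import numpy as np
import pytest

from hic3dqc.matrix_io import ContactMatrix
from hic3dqc.synthetic_data import sample_replicate, simulate_cell_type


def make_matrix(counts, resolution=40_000, chrom="chr1", is_raw=True):
    counts = np.asarray(counts, dtype=float)
    return ContactMatrix(chrom, resolution, counts, is_raw=is_raw)


def random_matrix(n, rng, max_count=20):
    upper = rng.integers(0, max_count + 1, size=(n, n))
    counts = np.triu(upper)
    counts = counts + counts.T - np.diag(np.diag(counts))
    return make_matrix(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_gt():
    return simulate_cell_type(60, seed=5)


@pytest.fixture(scope="session")
def small_replicate(small_gt):
    return sample_replicate(small_gt, 200_000, seed=6)


@pytest.fixture(scope="session")
def medium_replicate():
    gt = simulate_cell_type(200, seed=7)
    return sample_replicate(gt, 1_000_000, seed=8)
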