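import numpy as np
import pytest

from fourdn.genome_model import BinIndex, HiCMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_hic(values, resolution=100_000, chromosome="chrT", **kw):
    values = np.asarray(values, dtype=float)
    bins = BinIndex.from_range(chromosome, resolution, values.shape[0])
    return HiCMatrix(bins, values, **kw)


def random_hic(rng, n, density=1.0, scale=10.0):
    """Random symmetric non-negative matrix with zero diagonal."""
    A = rng.uniform(0.1, scale, size=(n, n))
    if density < 1.0:
        A *= rng.random((n, n)) < density
    A = np.triu(A, 1)
    A = A + A.T
    return make_hic(A)


@pytest.fixture
def hic_factory():
    return make_hic


@pytest.fixture
def random_hic_factory():
    return random_hic
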