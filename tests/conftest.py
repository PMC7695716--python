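import numpy as np
import pytest

from senloop.contacts import ContactMatrix, MatrixKind
from senloop.synthetic import SyntheticConfig, simulate_all

# a reduced genome keeps per-test simulation cheap while preserving every
# planted feature class
SMALL = dict(
    chrom_length=10_000_000,
    n_genes=40,
    n_enhancers=20,
    n_loops=6,
    n_diff_interactions=10,
    n_islands=6,
    n_tads=5,
    n_de_genes=12,
    n_ep_changes=4,
    library_size=8_000_000,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_symmetric_counts(n, rng, low=1, high=50):
    a = rng.integers(low, high, size=(n, n))
    m = np.triu(a) + np.triu(a, 1).T
    return m.astype(float)


@pytest.fixture()
def random_matrix(rng):
    vals = random_symmetric_counts(30, rng)
    return ContactMatrix(chrom="chr1", resolution=10_000, values=vals)
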