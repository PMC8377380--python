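import numpy as np
import pytest
from hypothesis import settings

from dsnfuse.core_io import SimilarityMatrix
from dsnfuse.synthetic import UniverseSpec, simulate_universe

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_universe():
    """Noiseless 40-drug universe with 4 planted clusters, all views informative."""
    return simulate_universe(UniverseSpec(n_drugs=40, n_clusters=4, seed=11))


@pytest.fixture(scope="session")
def noisy_universe():
    """60-drug universe with 3 clusters and moderate view noise plus ATC label noise."""
    return simulate_universe(
        UniverseSpec(
            n_drugs=60,
            n_clusters=3,
            se_noise=0.15,
            ap_noise=0.15,
            mutation_rate=0.05,
            label_noise=0.1,
            seed=5,
        )
    )


def block_matrix(sizes, within=0.9, between=0.1, seed=None, jitter=0.0):
    """Planted block-structured unit-scale similarity matrix."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    vals = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        noise = (noise + noise.T) / 2
        vals = np.clip(vals + noise, 0.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    drugs = [f"D{i:03d}" for i in range(n)]
    return SimilarityMatrix(drugs, vals, "unit"), labels + 1


@pytest.fixture
def two_block():
    return block_matrix([20, 20])
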