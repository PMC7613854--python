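import numpy as np
import pytest

from morbiclust import BinaryCohort, SimConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_two_block():
    """A small cohort with two well-separated classes on disjoint disease
    blocks (presence probability 0.9 inside the class block, 0.1 outside),
    plus the true labels."""
    rng = np.random.default_rng(42)
    n_per, d = 200, 10
    blocks = [np.arange(0, 5), np.arange(5, 10)]
    X = np.zeros((2 * n_per, d), dtype=np.int8)
    labels = np.repeat([0, 1], n_per)
    for cls, block in enumerate(blocks):
        rows = labels == cls
        probs = np.full(d, 0.1)
        probs[block] = 0.9
        X[rows] = rng.random((n_per, d)) < probs
    return BinaryCohort(X, [f"D{i}" for i in range(d)]), labels


@pytest.fixture
def small_sim():
    """A separable 3-cluster simulated cohort (high prevalence, low noise)."""
    return generate(SimConfig(n_patients=600, n_clusters=3, rho=0.0,
                              within_prevalence=0.9, noise_prob=0.0,
                              allow_overlap=False, seed=7))
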