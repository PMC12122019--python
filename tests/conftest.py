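import numpy as np
import pytest

from sparsevda.simulation import SimulationScenario, simulate_classification


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def small_sim():
    """A small, easy recovery problem: 6 informative of 50 features."""
    scenario = SimulationScenario(n=200, p=50, c=3, k_star=6,
                                  toeplitz_corr=0.1, snr=10.0, n_test=400,
                                  seed=11)
    return simulate_classification(scenario)


@pytest.fixture(scope="session")
def blobs():
    """Three well-separated Gaussian blobs in 5 dimensions."""
    rng = np.random.default_rng(7)
    centers = np.array([[4.0, 0, 0, 0, 0], [0, 4.0, 0, 0, 0],
                        [0, 0, 4.0, 0, 0]])
    X = np.vstack([centers[j] + rng.standard_normal((40, 5))
                   for j in range(3)])
    y = np.repeat([0, 1, 2], 40)
    return X, y


def random_design(rng, n, p, c, epsilon=0.3):
    """A design/label pair whose residuals straddle the epsilon ball."""
    X = rng.standard_normal((n, p))
    labels = rng.integers(0, c, size=n)
    Y = np.zeros((n, c))
    Y[np.arange(n), labels] = 1.0
    return X, Y
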