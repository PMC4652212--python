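import numpy as np
import pytest

from communal import SimSpec, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def three_blob_data():
    """Tight, well-separated 3-cluster data (gap >> diameter)."""
    rng = np.random.default_rng(99)
    centers = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 30.0]])
    labels = np.repeat([1, 2, 3], 10)
    X = centers[labels - 1] + rng.normal(scale=1.0, size=(30, 2))
    return X, labels


@pytest.fixture(scope="session")
def mini_sim():
    """Small separable simulated case used across tests (90 x 100, K=3)."""
    # overlap 1e-60 puts the centre separation (~33 sigma) far above the
    # within-cluster diameter (~ sigma * sqrt(2p) ~ 14 sigma): a true
    # separation >> diameter regime where every algorithm must agree
    spec = SimSpec(
        n_samples=90, k_true=3, p_inform=100, p_noise=0, overlap=1e-60, seed=7
    )
    return simulate(spec) + (spec,)
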