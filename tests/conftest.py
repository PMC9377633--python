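import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stable_random_w():
    """A generic random stable dense matrix (spectral abscissa < 1)."""
    gen = np.random.default_rng(7)
    W = gen.normal(0.0, 0.6 / np.sqrt(10), (10, 10))
    assert np.max(np.linalg.eigvals(W).real) < 1.0
    return W
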