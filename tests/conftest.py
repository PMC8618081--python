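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


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_network():
    """A compact model (T=6, N=3) with randomised weights for exact checks."""
    from basisimpute import DecompositionNetwork

    net = DecompositionNetwork(
        n_stations=3, window_length=6, hidden_dim=8, residual_dim=16,
        random_state=0,
    )
    gen = np.random.default_rng(99)
    for p in net.parameters():
        p[...] = gen.normal(0.0, 0.3, p.shape)
    return net


def random_window(gen, T=6, N=3, missing=0.25, loc=20.0, scale=4.0):
    values = gen.normal(loc, scale, (T, N))
    mask = (gen.random((T, N)) > missing).astype(float)
    if mask.sum() == 0:
        mask.ravel()[0] = 1.0
    return values, mask
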