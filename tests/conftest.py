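import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def circle360():
    """Unit circle sampled at 360 equal angles, CCW from (1, 0)."""
    t = 2 * np.pi * np.arange(360) / 360
    return np.column_stack([np.cos(t), np.sin(t)])


@pytest.fixture
def tooth_polygon():
    from occlumorph import tooth_outline
    return tooth_outline()


def random_configuration(rng, K):
    """Non-degenerate random landmark configuration."""
    return rng.normal(size=(K, 2))
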