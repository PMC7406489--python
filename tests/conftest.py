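import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lgcdesign import DEFAULT_GRID, REFERENCE_PARAMS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Reference population parameters used throughout the docs."""
    return REFERENCE_PARAMS


@pytest.fixture
def grid():
    """Five equidistant occasions, one-based coding."""
    return DEFAULT_GRID


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
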