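import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from hybridpsych import build_wv, cardinal_filter, intercardinal_filter


@pytest.fixture(scope="session")
def grid64():
    return (64, 64)


@pytest.fixture(scope="session")
def card64(grid64):
    return cardinal_filter(grid64)


@pytest.fixture(scope="session")
def inter64(grid64):
    return intercardinal_filter(grid64)


@pytest.fixture(scope="session")
def wv64(grid64):
    return build_wv(grid64)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
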