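import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def wm_mt():
    from epgx.presets import get_preset

    return get_preset("wm_mt")


@pytest.fixture
def myelin_bm():
    from epgx.presets import get_preset

    return get_preset("myelin_bm")


@pytest.fixture
def cn_mt():
    from epgx.presets import get_preset

    return get_preset("cn_mt")


@pytest.fixture
def single_wm():
    from epgx.presets import get_preset

    return get_preset("single_wm")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
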