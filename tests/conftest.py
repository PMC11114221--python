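import pytest
from hypothesis import settings

from aosim import (
    DeviceParams,
    default_affinity_profile,
)

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def profile():
    return default_affinity_profile()


@pytest.fixture(scope="session")
def device():
    """Moderately nonlinear device spanning the measured PA response window."""
    return DeviceParams(g_min=100.0, g_max=170.3, p_max=100, a_p=30.0, a_d=30.0)


@pytest.fixture(scope="session")
def linear_device():
    """Near-linear device: |A| far above P_max."""
    return DeviceParams(g_min=100.0, g_max=170.3, p_max=100, a_p=1e6, a_d=1e6)
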