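import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def adu_background():
    """ADU-scale background matching the simulator defaults.

    The simulator's photon-unit background (a=30, b=20, c=2) seen through
    gain 2 with offset 100 ADU.
    """
    from vercini import BackgroundParams

    return BackgroundParams(a=60.0, sigma1_px=6.0, b=40.0, sigma2_px=10.0,
                            c=104.0)
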