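import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lungmap as lm

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    return lm.default_schedule()


@pytest.fixture(scope="session")
def phantom():
    """Default 64x64 phantom used across estimator tests."""
    return lm.make_phantom(seed=7)


@pytest.fixture(scope="session")
def uniform_sv_phantom(phantom):
    """Phantom with spatially uniform SV = 0.2, for closed-form washin checks."""
    import dataclasses

    sv = np.where(phantom.lung_mask, 0.2, 0.0)
    return dataclasses.replace(phantom, sv_true=sv)
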