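import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adaptsim as ads

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params() -> ads.DesignParameters:
    return ads.pims_defaults()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
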