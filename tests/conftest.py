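import numpy as np
import pytest
from hypothesis import settings

from wormtherm import synthetic_worlds as sw

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def afd_ramp():
    return sw.default_ramp("afd")


@pytest.fixture
def awc_ramp():
    return sw.default_ramp("awc")
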