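import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nremdyn.params import OUParams, RatePopParams
from nremdyn.simulate import simulate_rate
from nremdyn.state_detect import detect_updown
from nremdyn.synthetic_data import SynthConfig, synth_swr_recording, synth_updown_recording

settings.register_profile(
    "deterministic", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: published best-fit operating points (neocortical / hippocampal)
NEOCORTICAL = RatePopParams(w=6.28, b=1.0, I=2.64)
HIPPOCAMPAL = RatePopParams(w=6.0, b=1.0, I=1.9)
#: simulation length used for duration statistics
STATS_DURATION = 60_000.0


@pytest.fixture(scope="session")
def noise():
    return OUParams()


@pytest.fixture(scope="session")
def nc_trace(noise):
    return simulate_rate(NEOCORTICAL, noise, STATS_DURATION, seed=101)


@pytest.fixture(scope="session")
def nc_states(nc_trace):
    return detect_updown(nc_trace)


@pytest.fixture(scope="session")
def hc_trace(noise):
    return simulate_rate(HIPPOCAMPAL, noise, STATS_DURATION, seed=102)


@pytest.fixture(scope="session")
def hc_states(hc_trace):
    return detect_updown(hc_trace)


@pytest.fixture(scope="session")
def updown_recording():
    return synth_updown_recording(SynthConfig(duration_s=150.0, seed=7))


@pytest.fixture(scope="session")
def swr_recording():
    return synth_swr_recording(SynthConfig(duration_s=150.0, swr_rate_hz=0.5, seed=8))
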