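import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from sprintfv import Athlete, SprintModelFit, predict_velocity
from sprintfv.fitting import RadarTrace


@pytest.fixture
def athlete():
    """Reference athlete: the study cohort's mean anthropometrics."""
    return Athlete("ref", body_mass=58.5, stature=1.74)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(mss=8.31, tau=1.25, rate=36.6, duration=5.0, noise_sd=0.0,
               rng=None, shift=0.0, **meta) -> RadarTrace:
    """Sample the mono-exponential model on a uniform clock (test helper)."""
    t = np.arange(0.0, duration, 1.0 / rate)
    fit = SprintModelFit(mss=mss, tau=tau)
    v = np.asarray(predict_velocity(np.maximum(t - shift, 0.0), fit))
    v[t < shift] = 0.0
    if noise_sd > 0:
        v = v + (rng or np.random.default_rng(0)).normal(0, noise_sd, v.size)
    return RadarTrace(time=t, velocity=v, nominal_rate=rate, **meta)
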