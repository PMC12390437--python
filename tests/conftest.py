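import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from stunwatch.datamodel import EEGTrace


@pytest.fixture
def flat_trace():
    """Constant 1 mV trace, 0-40 s at 100 Hz."""
    t = np.arange(0, 40, 0.01)
    return EEGTrace(t=t, v=np.ones_like(t), sample_rate=100.0)


def make_trace(levels: dict[tuple[float, float], float], sample_rate=100.0, t_end=40.0):
    """Piecewise-constant trace: amplitude `levels[(a, b)]` on [a, b)."""
    t = np.arange(0, t_end, 1.0 / sample_rate)
    v = np.zeros_like(t)
    for (a, b), amp in levels.items():
        v[(t >= a) & (t < b)] = amp
    return EEGTrace(t=t, v=v, sample_rate=sample_rate)
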