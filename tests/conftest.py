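import numpy as np
import pytest

from jvpulse.signal_core import TimeSeriesSignal, Units


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def random_signal(rng):
    """A 10 s noisy cardiac-like trace at dt = 0.008 s."""
    dt = 0.008
    t = np.arange(0, 10, dt)
    values = 1.0 + 0.07 * np.sin(2 * np.pi * 1.05 * t) + 0.01 * rng.normal(size=t.size)
    return TimeSeriesSignal(values, dt, label="csa", units=Units.cm2)


def make_tone(freq_hz, dt=0.01, duration=10.0, amp=1.0, phase=0.0, mean=0.0):
    t = np.arange(0, duration, dt)
    return TimeSeriesSignal(mean + amp * np.sin(2 * np.pi * freq_hz * t + phase), dt)
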