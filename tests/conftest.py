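import numpy as np
import pytest

from posturekit import SignalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def sine_record():
    """Unit-amplitude 100 Hz sinusoid at fs=1000, 2 s."""
    fs = 1000.0
    t = np.arange(int(2 * fs)) / fs
    x = np.sin(2 * np.pi * 100.0 * t)
    return SignalRecord(x[:, None], fs, ["ch1"])


@pytest.fixture
def noise_record(rng):
    fs = 1000.0
    return SignalRecord(rng.standard_normal((4000, 2)), fs, ["ch1", "ch2"])
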