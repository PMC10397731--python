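import numpy as np
import pytest

from rhythmcode import SignalSegment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone_segment(freq, fs=128.0, duration=2.0, amp=1.0, **meta):
    t = np.arange(int(round(duration * fs))) / fs
    return SignalSegment(amp * np.cos(2 * np.pi * freq * t), fs, **meta)


def chirp_segment(f0=5.0, f1=25.0, fs=128.0, duration=2.0):
    t = np.arange(int(round(duration * fs))) / fs
    phase = 2 * np.pi * (f0 * t + (f1 - f0) / (2 * duration) * t**2)
    return SignalSegment(np.cos(phase), fs)


@pytest.fixture
def tone_10hz():
    return tone_segment(10.0)


@pytest.fixture
def chirp():
    return chirp_segment()
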