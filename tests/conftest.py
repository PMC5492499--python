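import numpy as np
import pytest

from uwbvitals.frames_io import FrameMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_frames(rng):
    """A 100x256 random frame matrix with default metadata."""
    return FrameMatrix(data=rng.normal(0.0, 1.0, (100, 256)))


def sinusoid(freq_hz, fs, n, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2.0 * np.pi * freq_hz * t + phase)
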