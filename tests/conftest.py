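import numpy as np
import pytest

from neurocarousel import LfpRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def sine_recording(freq: float, duration: float = 10.0, fs: float = 2000.0,
                   amp: float = 1.0, n_channels: int = 1) -> LfpRecording:
    """Pure sinusoid test recording."""
    t = np.arange(int(round(duration * fs))) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return LfpRecording([f"ch{i}" for i in range(n_channels)],
                        np.tile(x, (n_channels, 1)), fs)


@pytest.fixture
def sine_factory():
    return sine_recording
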