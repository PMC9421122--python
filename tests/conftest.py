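import numpy as np
import pytest

from pcgbench.spectral import MelSpectrogram, SpectrogramImage
from pcgbench.synthetic import AudioRecording, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def normal_rec():
    """A 30 s normal recording at a pinned 75 bpm heart rate."""
    return generate_recording(0, seed=11, heart_rate=75.0, duration=30.0)


@pytest.fixture(scope="session")
def tone():
    """Pure 220 Hz tone, 10 s at 2 kHz."""
    sr = 2000
    t = np.arange(0, 10, 1 / sr)
    return AudioRecording(0.8 * np.sin(2 * np.pi * 220.0 * t), sr, 0, "tone220")


@pytest.fixture
def random_image(rng):
    return SpectrogramImage(rng.integers(0, 256, (100, 180, 3)).astype(np.uint8))


@pytest.fixture
def random_mel(rng):
    values = rng.uniform(-80.0, 0.0, (128, 230))
    values.flat[rng.integers(0, values.size)] = 0.0  # pin the 0 dB reference
    return MelSpectrogram(values, np.arange(230) * 0.128, np.linspace(5, 780, 128))


def spectral_peak_hz(samples, sample_rate):
    """Periodogram peak frequency — the oracle used for pitch checks."""
    from scipy.signal import periodogram

    f, p = periodogram(samples, sample_rate)
    return f[int(np.argmax(p))]
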