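"""Mel-spectrogram construction and fixed-size color image rendering.

Audio is framed with a 512-sample Hann window at hop 256 (no padding), passed
through a 512-point FFT, pooled onto a triangular Mel filterbank built on the
scale Mel = 2595*log10(1 + f/break) with break = 500 Hz by default (the
conventional scale uses 700; both are supported), converted to dB re the
maximum (20*log10(A/A_max), so the maximum maps to 0 dB), floored at -80 dB,
mapped through a monotone colormap, and bicubic-resized to a 100 x 180 x 3
RGB image with low frequencies at the bottom row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.signal.windows import hann

from pcgbench.synthetic import AudioRecording

IMAGE_HEIGHT = 100
IMAGE_WIDTH = 180


@dataclass(frozen=True)
class SpectrogramParams:
    window_length: int = 512
    hop: int = 256
    n_fft: int = 512
    n_mels: int = 128
    mel_coeff: float = 2595.0
    mel_break_hz: float = 500.0
    db_floor: float = -80.0
    db_convention: str = "amplitude"  # 20*log10; "power" switches to 10*log10
    colormap: str = "inferno"

    def validate(self) -> None:
        if self.hop > self.window_length:
            raise ValueError("hop must not exceed window length")
        if self.n_fft < self.window_length:
            raise ValueError("n_fft must be >= window length")
        if self.mel_break_hz <= 0:
            raise ValueError("mel_break_hz must be positive")
        if self.db_floor >= 0:
            raise ValueError("db_floor must be negative")
        if self.db_convention not in ("amplitude", "power"):
            raise ValueError("db_convention must be 'amplitude' or 'power'")


@dataclass
class MelSpectrogram:
    """dB-scaled Mel spectrogram: rows = frequency channels, columns = time steps."""

    values: np.ndarray  # (n_mels, n_frames)
    frame_times: np.ndarray
    mel_centers: np.ndarray
    db_floor: float = -80.0

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MelSpectrogram":
        return MelSpectrogram(
            self.values.copy(), self.frame_times.copy(), self.mel_centers.copy(), self.db_floor
        )


@dataclass
class SpectrogramImage:
    """Fixed-size 8-bit RGB rendering; row 0 is the highest frequency."""

    pixels: np.ndarray  # (100, 180, 3) uint8
    colormap_id: str = "inferno"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_HEIGHT, IMAGE_WIDTH, 3):
            raise ValueError(f"pixels must be {IMAGE_HEIGHT}x{IMAGE_WIDTH}x3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")

    def copy(self) -> "SpectrogramImage":
        return SpectrogramImage(self.pixels.copy(), self.colormap_id, self.source_id)


def hz_to_mel(f, p: SpectrogramParams = SpectrogramParams()):
    """Mel = coeff * log10(1 + f / break)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    return p.mel_coeff * np.log10(1.0 + f / p.mel_break_hz)


def mel_to_hz(m, p: SpectrogramParams = SpectrogramParams()):
    m = np.asarray(m, dtype=float)
    return p.mel_break_hz * (10.0 ** (m / p.mel_coeff) - 1.0)


def power_spectrogram(rec: AudioRecording, p: SpectrogramParams = SpectrogramParams()) -> np.ndarray:
    """Squared-magnitude STFT, shape (n_fft//2 + 1, n_frames), no padding.

    Frame count = floor((len - window) / hop) + 1.
    """
    p.validate()
    x = rec.samples
    if x.size < p.window_length:
        raise ValueError("signal shorter than one analysis window")
    frames = np.lib.stride_tricks.sliding_window_view(x, p.window_length)[:: p.hop]
    win = hann(p.window_length, sym=False)
    spec = np.fft.rfft(frames * win, n=p.n_fft, axis=1)
    return (np.abs(spec) ** 2).T


def mel_filterbank(sample_rate: int, p: SpectrogramParams = SpectrogramParams()) -> np.ndarray:
    """Triangular filters equally spaced on the configured Mel scale, (n_mels, n_bins)."""
    n_bins = p.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_bins)
    mel_edges = np.linspace(0.0, float(hz_to_mel(sample_rate / 2.0, p)), p.n_mels + 2)
    hz_edges = mel_to_hz(mel_edges, p)
    fb = np.zeros((p.n_mels, n_bins))
    for i in range(p.n_mels):
        lo, center, hi = hz_edges[i : i + 3]
        up = (fft_freqs - lo) / max(center - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - center, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def to_mel_db(
    spec: np.ndarray,
    sample_rate: int,
    p: SpectrogramParams = SpectrogramParams(),
    hop_seconds: float | None = None,
) -> MelSpectrogram:
    """Pool a linear power spectrogram onto the Mel scale and convert to dB.

    The maximum Mel cell is the 0 dB reference; values are clamped at the
    configured floor.
    """
    p.validate()
    spec = np.asarray(spec, dtype=float)
    if spec.size == 0 or not np.any(spec > 0):
        raise ValueError("spectrogram has no positive energy")
    fb = mel_filterbank(sample_rate, p)
    mel_power = fb @ spec
    ref = float(mel_power.max())
    scale = 10.0 if p.db_convention == "power" else 20.0
    amp = np.sqrt(np.maximum(mel_power, 0.0))
    ref_amp = np.sqrt(ref)
    with np.errstate(divide="ignore"):
        db = scale * np.log10(np.maximum(amp / ref_amp, 1e-20))
    db = np.maximum(db, p.db_floor)
    hop_s = hop_seconds if hop_seconds is not None else p.hop / sample_rate
    frame_times = np.arange(spec.shape[1]) * hop_s + 0.5 * p.window_length / sample_rate
    mel_centers = np.linspace(0.0, float(hz_to_mel(sample_rate / 2.0, p)), p.n_mels + 2)[1:-1]
    return MelSpectrogram(db, frame_times, mel_centers, p.db_floor)


def mel_spectrogram(
    rec: AudioRecording, p: SpectrogramParams = SpectrogramParams()
) -> MelSpectrogram:
    """Convenience chain: power spectrogram -> Mel pooling -> dB."""
    return to_mel_db(power_spectrogram(rec, p), rec.sample_rate, p)


def render_image(
    mel: MelSpectrogram, colormap_id: str = "inferno", source_id: str = ""
) -> SpectrogramImage:
    """Colormap the dB matrix and bicubic-resize to the fixed 100 x 180 frame.

    dB values are mapped linearly from [db_floor, 0] to the colormap domain;
    the row order is flipped so low frequencies sit at the bottom of the image.
    """
    if mel.values.size == 0:
        raise ValueError("empty Mel spectrogram")
    try:
        cmap = colormaps[colormap_id]
    except KeyError as exc:
        raise ValueError(f"unknown colormap {colormap_id!r}") from exc
    norm = (mel.values - mel.db_floor) / (0.0 - mel.db_floor)
    norm = np.clip(norm, 0.0, 1.0)
    rgb = cmap(norm)[..., :3]  # drop alpha
    rgb = rgb[::-1, :, :]  # row 0 = highest frequency
    img8 = np.round(rgb * 255.0).astype(np.uint8)
    resized = np.asarray(
        Image.fromarray(img8).resize((IMAGE_WIDTH, IMAGE_HEIGHT), Image.BICUBIC)
    )
    return SpectrogramImage(resized, colormap_id=colormap_id, source_id=source_id)


def save_png(img: SpectrogramImage, path) -> None:
    Image.fromarray(img.pixels).save(str(path), format="PNG")


def recording_to_image(
    rec: AudioRecording, p: SpectrogramParams = SpectrogramParams()
) -> SpectrogramImage:
    """Full audio -> image chain used by the experiment runner."""
    return render_image(mel_spectrogram(rec, p), colormap_id=p.colormap, source_id=rec.record_id)
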