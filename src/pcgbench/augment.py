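"""The nine data-augmentation methods and one-to-one dataset doubling.

Audio level: pitch shift / time stretch (phase vocoder, so the two operations
are independent: shifting preserves duration, stretching preserves pitch) and
additive white Gaussian noise at 0 dB SNR (noise sigma = signal RMS).

Image level: horizontal/vertical flips, saturation-value (SV) perturbation by
linear blending, PCA color augmentation (RGB covariance eigen-perturbation
with alpha ~ N(800, 10)), and random color filters drawn from a registry of
150 color-space conversions.

Spectrogram level: time/frequency masking (three masks per axis, widths
uniform on [0, 20], masked cells set to 0 dB).

Every method preserves the class label. ``augment_training_set`` applies one
method in one-to-one correspondence: N training items become exactly 2N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal.windows import hann

from pcgbench import colorspaces
from pcgbench.preprocess import normalize_amplitude
from pcgbench.spectral import MelSpectrogram, SpectrogramImage
from pcgbench.synthetic import AudioRecording

AUDIO_METHODS = ("pitch_time", "noise")
MEL_METHODS = ("mask",)
IMAGE_METHODS = ("hflip", "vflip", "sv", "pca", "color_filter", "hflip_pca", "hflip_sv")
ALL_METHODS = AUDIO_METHODS + IMAGE_METHODS[:5] + MEL_METHODS + ("hflip_pca", "hflip_sv")

#: luma weights used for the grayscale blending target of the saturation pass
_LUMA = np.array([0.299, 0.587, 0.114])


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PitchTimeParams:
    p: int  # signed semitones, |p| in 1..10 when sampled
    t: float  # stretch factor in [0.5, 2.0] when sampled

    def validate(self) -> None:
        if not (isinstance(self.p, (int, np.integer)) and 1 <= abs(int(self.p)) <= 10):
            raise ValueError("|p| must be an integer in 1..10")
        if not (0.5 <= self.t <= 2.0):
            raise ValueError("t must lie in [0.5, 2.0]")


@dataclass(frozen=True)
class SvPerturbParams:
    alpha_brightness: float  # uniform draw in [0.5, 2]
    alpha_saturation: float  # uniform draw in [0.1, 2]

    def validate(self) -> None:
        if not (0.5 <= self.alpha_brightness <= 2.0):
            raise ValueError("alpha_brightness out of [0.5, 2]")
        if not (0.1 <= self.alpha_saturation <= 2.0):
            raise ValueError("alpha_saturation out of [0.1, 2]")


@dataclass(frozen=True)
class MaskParams:
    """Explicit mask placement: lists of (start, width) per axis, fill in dB."""

    freq_masks: tuple  # ((f0, f), ...) over frequency channels (rows)
    time_masks: tuple  # ((t0, t), ...) over time steps (columns)
    fill_db: float = 0.0


@dataclass
class AugmentationSpec:
    """Method identifier plus the sampled parameters, for reproducibility."""

    method: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"method": self.method, "params": self.params, "seed": self.seed}


@dataclass
class TrainingItem:
    """One training example at whatever representation the arm operates on."""

    record_id: str
    label: int
    payload: Any  # AudioRecording | MelSpectrogram | SpectrogramImage
    source_id: str | None = None
    spec: AugmentationSpec | None = None


# ---------------------------------------------------------------------------
# phase vocoder: time stretch and pitch shift
# ---------------------------------------------------------------------------

_PV_WIN = 512
_PV_HOP = 128  # win/4: tight overlap for clean resynthesis


def _stft(x: np.ndarray) -> np.ndarray:
    pad = _PV_WIN // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = 1 + (xp.size - _PV_WIN) // _PV_HOP
    frames = np.lib.stride_tricks.sliding_window_view(xp, _PV_WIN)[:: _PV_HOP][:n_frames]
    win = hann(_PV_WIN, sym=False)
    return np.fft.rfft(frames * win, axis=1).T  # (bins, frames)


def _istft(D: np.ndarray, length: int) -> np.ndarray:
    win = hann(_PV_WIN, sym=False)
    n_frames = D.shape[1]
    total = _PV_WIN + _PV_HOP * (n_frames - 1)
    y = np.zeros(total)
    wsum = np.zeros(total)
    frames = np.fft.irfft(D, n=_PV_WIN, axis=0)
    for t in range(n_frames):
        s = t * _PV_HOP
        y[s : s + _PV_WIN] += frames[:, t] * win
        wsum[s : s + _PV_WIN] += win**2
    y = y / np.maximum(wsum, 1e-12)
    pad = _PV_WIN // 2
    y = y[pad:]
    if y.size < length:
        y = np.pad(y, (0, length - y.size))
    return y[:length]


def _phase_vocoder(D: np.ndarray, rate: float) -> np.ndarray:
    """Resample the STFT in time by ``rate`` with phase accumulation."""
    n_bins, n_frames = D.shape
    steps = np.arange(0, n_frames, rate)
    idx = steps.astype(int)
    frac = steps - idx
    Dp = np.pad(D, [(0, 0), (0, 2)])
    mag = (1.0 - frac) * np.abs(Dp[:, idx]) + frac * np.abs(Dp[:, idx + 1])
    phi_adv = 2.0 * np.pi * _PV_HOP * np.arange(n_bins) / _PV_WIN
    dphi = np.angle(Dp[:, 1:]) - np.angle(Dp[:, :-1]) - phi_adv[:, None]
    dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
    dphi += phi_adv[:, None]
    increments = dphi[:, idx]
    phases = np.angle(D[:, :1]) + np.concatenate(
        [np.zeros((n_bins, 1)), np.cumsum(increments[:, :-1], axis=1)], axis=1
    )
    return mag * np.exp(1j * phases)


def time_stretch(rec: AudioRecording, t: float) -> AudioRecording:
    """Pitch-preserving stretch: output duration = t x input duration."""
    if t <= 0:
        raise ValueError("stretch factor must be positive")
    if rec.samples.size < _PV_WIN:
        raise ValueError("signal too short to stretch")
    out_len = int(round(rec.samples.size * t))
    y = _istft(_phase_vocoder(_stft(rec.samples), 1.0 / t), out_len)
    prov = {**rec.provenance, "kind": "augmented", "method": "time_stretch", "t": float(t)}
    return rec.copy_with(samples=y, provenance=prov)


def pitch_shift(rec: AudioRecording, p: float) -> AudioRecording:
    """Duration-preserving shift of all frequencies by 2**(p/12)."""
    if rec.samples.size < _PV_WIN:
        raise ValueError("signal too short to pitch-shift")
    r = 2.0 ** (p / 12.0)
    n = rec.samples.size
    if r == 1.0:
        stretched = rec.samples
    else:
        m = int(round(n * r))
        stretched = _istft(_phase_vocoder(_stft(rec.samples), 1.0 / r), m)
    # play the stretched signal back at the original length: frequencies x r
    m = stretched.size
    pos = np.linspace(0.0, m - 1.0, n)
    y = np.interp(pos, np.arange(m), stretched)
    prov = {**rec.provenance, "kind": "augmented", "method": "pitch_shift", "p": float(p)}
    return rec.copy_with(samples=y, provenance=prov)


def sample_pitch_time_params(rng: np.random.Generator) -> PitchTimeParams:
    """p = +/- integer in 1..10 (sign equiprobable), t ~ U[0.5, 2.0]."""
    p = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
    t = float(rng.uniform(0.5, 2.0))
    return PitchTimeParams(p=p, t=t)


def pitch_time_augment(
    rec: AudioRecording, params: PitchTimeParams | None = None, rng=None
) -> tuple[AudioRecording, PitchTimeParams]:
    """Method 1: pitch shift by p semitones, then stretch/compress by t."""
    if params is None:
        params = sample_pitch_time_params(_as_rng(rng))
    params.validate()
    out = time_stretch(pitch_shift(rec, params.p), params.t)
    out.provenance = {
        **rec.provenance,
        "kind": "augmented",
        "method": "pitch_time",
        "p": params.p,
        "t": params.t,
    }
    return out, params


# ---------------------------------------------------------------------------
# noise injection
# ---------------------------------------------------------------------------


def compute_rms(x) -> float:
    """Root mean square sqrt(sum(x_i^2) / n)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("RMS of an empty sequence is undefined")
    return float(np.sqrt(np.mean(x**2)))


def inject_awgn(
    rec: AudioRecording, rng=None, *, renormalize: bool = True
) -> AudioRecording:
    """Method 2: add white Gaussian noise with sigma = RMS(signal) (0 dB SNR).

    The sum is re-normalized by peak division so samples stay within [-1, 1];
    pass ``renormalize=False`` to inspect the raw sum.
    """
    sigma = compute_rms(rec.samples)
    if sigma == 0.0:
        raise ValueError("cannot set noise level from a zero-RMS signal")
    noise = _as_rng(rng).normal(0.0, sigma, rec.samples.size)
    out = rec.copy_with(samples=rec.samples + noise)
    if renormalize:
        out = normalize_amplitude(out)
    out.provenance = {**rec.provenance, "kind": "augmented", "method": "noise", "sigma": sigma}
    return out


# ---------------------------------------------------------------------------
# image flips
# ---------------------------------------------------------------------------


def hflip(img: SpectrogramImage) -> SpectrogramImage:
    """Pixel (x, y) -> (width - x - 1, y); the frequency axis is untouched."""
    out = img.copy()
    out.pixels = np.ascontiguousarray(img.pixels[:, ::-1, :])
    return out


def vflip(img: SpectrogramImage) -> SpectrogramImage:
    """Pixel (x, y) -> (x, height - y - 1)."""
    out = img.copy()
    out.pixels = np.ascontiguousarray(img.pixels[::-1, :, :])
    return out


# ---------------------------------------------------------------------------
# color-space operations
# ---------------------------------------------------------------------------


def rgb_to_hsv(pixel) -> np.ndarray:
    """RGB in [0,255] -> (H degrees in [0,360), S in [0,1], V in [0,1]).

    Direct piecewise evaluation: R'=R/255 etc., Cmax/Cmin/Delta, the Cmax case
    split for H, S = Delta/Cmax (0 when Cmax = 0), V = Cmax. Gray pixels
    (Delta = 0) take H = 0 by convention. Accepts a single pixel or an
    (..., 3) array.
    """
    arr = np.asarray(pixel, dtype=float) / 255.0
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    cmax = np.maximum.reduce([r, g, b])
    cmin = np.minimum.reduce([r, g, b])
    delta = cmax - cmin
    safe = np.where(delta == 0, 1.0, delta)
    h = np.zeros_like(cmax)
    is_r = (cmax == r) & (delta > 0)
    is_g = (cmax == g) & (delta > 0) & ~is_r
    is_b = (cmax == b) & (delta > 0) & ~is_r & ~is_g
    h = np.where(is_r, 60.0 * np.mod((g - b) / safe, 6.0), h)
    h = np.where(is_g, 60.0 * ((b - r) / safe + 2.0), h)
    h = np.where(is_b, 60.0 * ((r - g) / safe + 4.0), h)
    s = np.where(cmax == 0, 0.0, delta / np.where(cmax == 0, 1.0, cmax))
    out = np.stack([h, s, cmax], axis=-1)
    return out[0] if single else out


def sample_sv_params(rng: np.random.Generator) -> SvPerturbParams:
    return SvPerturbParams(
        alpha_brightness=float(rng.uniform(0.5, 2.0)),
        alpha_saturation=float(rng.uniform(0.1, 2.0)),
    )


def sv_perturb(
    img: SpectrogramImage, params: SvPerturbParams | None = None, rng=None
) -> tuple[SpectrogramImage, SvPerturbParams]:
    """Method 4.1: blend = Blend*(1 - alpha) + Original*alpha, twice.

    Brightness pass blends with an all-black image (so the image is scaled by
    alpha_brightness); saturation pass blends with the image's own grayscale.
    Applied sequentially in that order; channels clipped to [0, 255].
    """
    if params is None:
        params = sample_sv_params(_as_rng(rng))
    params.validate()
    x = img.pixels.astype(np.float64)
    x = x * params.alpha_brightness  # black * (1 - a) + x * a
    gray = (x @ _LUMA)[..., None] * np.ones(3)
    x = gray * (1.0 - params.alpha_saturation) + x * params.alpha_saturation
    out = img.copy()
    out.pixels = np.round(np.clip(x, 0.0, 255.0)).astype(np.uint8)
    return out, params


def pca_color_augment(
    img: SpectrogramImage,
    alpha: float | None = None,
    rng=None,
    *,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[SpectrogramImage, float]:
    """Method 4.2: shift every pixel along the RGB covariance eigenvectors.

    The 3x3 covariance of the image's raw 0-255 RGB values is
    eigen-decomposed; a single alpha ~ N(800, 10) multiplies the eigenvalues,
    and the perturbation P @ (alpha * lambda) is added to every pixel, then
    clipped to [0, 255]. ``stats=(eigvals, eigvecs)`` substitutes dataset-wide
    statistics for the per-image default.
    """
    if alpha is None:
        alpha = float(_as_rng(rng).normal(800.0, 10.0))
    flat = img.pixels.reshape(-1, 3).astype(np.float64)
    if stats is not None:
        eigvals, eigvecs = stats
    else:
        cov = np.cov(flat.T)
        eigvals, eigvecs = np.linalg.eigh(cov)
        eigvals = np.maximum(eigvals, 0.0)
        eigvecs = _fix_eigvec_signs(eigvecs)
    delta = eigvecs @ (alpha * eigvals)
    out = img.copy()
    out.pixels = np.round(np.clip(flat + delta, 0.0, 255.0)).astype(np.uint8).reshape(
        img.pixels.shape
    )
    return out, float(alpha)


def _fix_eigvec_signs(vecs: np.ndarray) -> np.ndarray:
    """Orient each eigenvector so its largest-magnitude component is positive.

    Eigenvector signs are otherwise arbitrary, and the perturbation direction
    depends on them; this makes the augmentation well defined.
    """
    out = vecs.copy()
    for i in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, i])))
        if out[j, i] < 0:
            out[:, i] = -out[:, i]
    return out


def random_color_filter(
    img: SpectrogramImage, rng=None, index: int | None = None
) -> tuple[SpectrogramImage, str]:
    """Method 4.3: apply one of 150 registered color-space conversions."""
    reg = colorspaces.registry()
    if len(reg) != colorspaces.REGISTRY_SIZE:
        raise ValueError("color-conversion registry has unexpected size")
    if index is None:
        index = int(_as_rng(rng).integers(len(reg)))
    name, func = reg[index]
    out = img.copy()
    out.pixels = np.ascontiguousarray(func(img.pixels))
    return out, name


# ---------------------------------------------------------------------------
# time/frequency masking
# ---------------------------------------------------------------------------


def sample_mask_params(
    mel: MelSpectrogram, rng: np.random.Generator, *, n_masks: int = 3, max_width: int = 20
) -> MaskParams:
    """Three frequency + three time masks, integer widths uniform on [0, 20].

    Frequency starts are drawn from (0, v - f), time starts from [0, tau - t],
    matching the printed bounds; masks may overlap.
    """
    v, tau = mel.n_channels, mel.n_steps
    if v <= max_width or tau <= max_width:
        raise ValueError("spectrogram too small for the mask bounds")
    freq, tim = [], []
    for _ in range(n_masks):
        f = int(rng.integers(0, max_width + 1))
        f0 = int(rng.integers(1, v - f))
        freq.append((f0, f))
    for _ in range(n_masks):
        t = int(rng.integers(0, max_width + 1))
        t0 = int(rng.integers(0, tau - t + 1))
        tim.append((t0, t))
    return MaskParams(freq_masks=tuple(freq), time_masks=tuple(tim), fill_db=0.0)


def time_frequency_mask(
    mel: MelSpectrogram, rng=None, params: MaskParams | None = None
) -> tuple[MelSpectrogram, MaskParams]:
    """Method 5: set masked rows/columns to the fill value (0 dB by default).

    A 0 dB fill renders at the colormap maximum, producing the bright bars on
    the resulting image.
    """
    if params is None:
        params = sample_mask_params(mel, _as_rng(rng))
    out = mel.copy()
    v, tau = out.n_channels, out.n_steps
    for f0, f in params.freq_masks:
        if not (0 <= f0 and f0 + f <= v):
            raise ValueError("frequency mask outside the matrix")
        out.values[f0 : f0 + f, :] = params.fill_db
    for t0, t in params.time_masks:
        if not (0 <= t0 and t0 + t <= tau):
            raise ValueError("time mask outside the matrix")
        out.values[:, t0 : t0 + t] = params.fill_db
    return out, params


# ---------------------------------------------------------------------------
# composition and one-to-one doubling
# ---------------------------------------------------------------------------

_IMAGE_OPS = {"hflip", "vflip", "sv", "pca", "color_filter"}


def compose_method(img: SpectrogramImage, first: str, then: str, rng=None):
    """Apply two image-level methods in order (PCA->hflip and SV->hflip arms)."""
    if first not in _IMAGE_OPS or then not in _IMAGE_OPS:
        raise ValueError(f"compose_method requires image-level methods, got {first}, {then}")
    rng = _as_rng(rng)
    params: dict = {}
    out = img
    for stage, name in (("first", first), ("then", then)):
        out, par = _apply_image_method(out, name, rng)
        params[stage] = {"method": name, **par}
    return out, params


def _apply_image_method(img: SpectrogramImage, method: str, rng) -> tuple[SpectrogramImage, dict]:
    if method == "hflip":
        return hflip(img), {}
    if method == "vflip":
        return vflip(img), {}
    if method == "sv":
        out, p = sv_perturb(img, rng=rng)
        return out, {"alpha_brightness": p.alpha_brightness, "alpha_saturation": p.alpha_saturation}
    if method == "pca":
        out, alpha = pca_color_augment(img, rng=rng)
        return out, {"alpha": alpha}
    if method == "color_filter":
        out, name = random_color_filter(img, rng=rng)
        return out, {"conversion": name}
    raise ValueError(f"unknown image method {method}")


def method_level(method: str) -> str:
    """Representation a method operates on: 'audio', 'mel', or 'image'."""
    if method in AUDIO_METHODS:
        return "audio"
    if method in MEL_METHODS:
        return "mel"
    if method in IMAGE_METHODS:
        return "image"
    raise ValueError(f"unknown augmentation method {method!r}")


def apply_method(payload, method: str, rng) -> tuple[Any, dict]:
    """Dispatch one augmentation method on its expected payload type."""
    level = method_level(method)
    if level == "audio":
        if not isinstance(payload, AudioRecording):
            raise TypeError(f"method {method} expects an AudioRecording")
        if method == "pitch_time":
            out, p = pitch_time_augment(payload, rng=rng)
            return out, {"p": p.p, "t": p.t}
        out = inject_awgn(payload, rng=rng)
        return out, {"sigma": out.provenance["sigma"]}
    if level == "mel":
        if not isinstance(payload, MelSpectrogram):
            raise TypeError("method mask expects a MelSpectrogram")
        out, params = time_frequency_mask(payload, rng=rng)
        return out, {"freq_masks": params.freq_masks, "time_masks": params.time_masks}
    if not isinstance(payload, SpectrogramImage):
        raise TypeError(f"method {method} expects a SpectrogramImage")
    if method == "hflip_pca":
        return compose_method(payload, "pca", "hflip", rng)
    if method == "hflip_sv":
        return compose_method(payload, "sv", "hflip", rng)
    return _apply_image_method(payload, method, rng)


def augment_training_set(
    items: list[TrainingItem], method: str, master_seed: int
) -> list[TrainingItem]:
    """One-to-one doubling: every training item gains one augmented twin.

    Labels are copied; each twin's provenance cites its source record and its
    sampled parameters. Output size is exactly 2N.
    """
    method_level(method)  # validate early
    if not items:
        raise ValueError("training set must be nonempty")
    out = list(items)
    for i, item in enumerate(items):
        tag = int.from_bytes(method.encode()[:4].ljust(4, b"\0"), "little")
        seed = int(
            np.random.SeedSequence((int(master_seed), i, tag)).generate_state(1)[0] % (2**31 - 1)
        )
        rng = np.random.default_rng(seed)
        payload, params = apply_method(item.payload, method, rng)
        out.append(
            TrainingItem(
                record_id=f"{item.record_id}::aug",
                label=item.label,
                payload=payload,
                source_id=item.record_id,
                spec=AugmentationSpec(method=method, params=params, seed=seed),
            )
        )
    return out


def _as_rng(rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng
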