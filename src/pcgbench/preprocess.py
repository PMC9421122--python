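"""Signal conditioning: band-pass filter, length policy, amplitude normalization.

Recordings are processed in a fixed order: a third-order Butterworth band-pass
of 20-500 Hz (applied zero-phase, so S1/S2 onsets are not delayed), a length
policy that discards recordings under 8 s and truncates those over 30 s, and
peak normalization x / max(|x|) so every surviving recording has max absolute
amplitude exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from pcgbench.synthetic import AudioRecording, DatasetManifest, read_wav

logger = logging.getLogger(__name__)


class Discard:
    """Sentinel returned by the length policy for recordings under the minimum."""

    def __repr__(self) -> str:  # pragma: no cover
        return "DISCARD"


DISCARD = Discard()


@dataclass(frozen=True)
class PreprocessConfig:
    filter_order: int = 3
    passband: tuple[float, float] = (20.0, 500.0)
    min_duration: float = 8.0
    max_duration: float = 30.0

    def validate(self, sample_rate: float | None = None) -> None:
        lo, hi = self.passband
        if not (0 < lo < hi):
            raise ValueError("passband must satisfy 0 < low < high")
        if sample_rate is not None and hi >= sample_rate / 2:
            raise ValueError("passband high edge must be below Nyquist")
        if self.min_duration > self.max_duration:
            raise ValueError("min_duration must not exceed max_duration")


def bandpass_filter(rec: AudioRecording, cfg: PreprocessConfig = PreprocessConfig()) -> AudioRecording:
    """Butterworth band-pass of the configured order, applied forward-backward.

    Zero-phase filtering squares the magnitude response of the stated design
    order but introduces no group delay.
    """
    cfg.validate(rec.sample_rate)
    sos = signal.butter(
        cfg.filter_order, cfg.passband, btype="bandpass", fs=rec.sample_rate, output="sos"
    )
    y = signal.sosfiltfilt(sos, rec.samples)
    return rec.copy_with(samples=y)


def apply_length_policy(
    rec: AudioRecording, cfg: PreprocessConfig = PreprocessConfig()
) -> AudioRecording | Discard:
    """Discard under ``min_duration``; truncate over ``max_duration``; else keep.

    Boundary convention: exactly 8 s is kept, exactly 30 s is kept untruncated.
    """
    cfg.validate()
    if rec.duration < cfg.min_duration:
        return DISCARD
    max_n = int(round(cfg.max_duration * rec.sample_rate))
    if rec.samples.size > max_n:
        return rec.copy_with(samples=rec.samples[:max_n].copy())
    return rec


def normalize_amplitude(rec: AudioRecording) -> AudioRecording:
    """Peak normalization x / max(|x|); undefined (error) for all-zero input."""
    peak = float(np.max(np.abs(rec.samples)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    return rec.copy_with(samples=rec.samples / peak)


def preprocess_recording(
    rec: AudioRecording, cfg: PreprocessConfig = PreprocessConfig()
) -> AudioRecording | Discard:
    """Filter -> length policy -> normalize, in that fixed order."""
    filtered = bandpass_filter(rec, cfg)
    kept = apply_length_policy(filtered, cfg)
    if kept is DISCARD:
        return DISCARD
    return normalize_amplitude(kept)


def preprocess_pipeline(
    manifest: DatasetManifest,
    cfg: PreprocessConfig = PreprocessConfig(),
    *,
    on_error: str = "skip",
) -> tuple[list[AudioRecording], DatasetManifest]:
    """Run the conditioning chain over a manifest of WAV files.

    Returns the surviving in-memory recordings and a filtered manifest.
    ``on_error`` = 'skip' logs and drops unreadable files; 'abort' raises.
    """
    survivors: list[AudioRecording] = []
    rows = []
    for row in manifest.records:
        try:
            rec = read_wav(row["path"], label=int(row["label"]), record_id=row["record_id"])
        except Exception:
            if on_error == "abort":
                raise
            logger.warning("skipping unreadable file %s", row["path"])
            continue
        out = preprocess_recording(rec, cfg)
        if out is DISCARD:
            continue
        survivors.append(out)
        rows.append({**row, "duration_s": round(out.duration, 6)})
    filtered = DatasetManifest(records=rows, seed=manifest.seed)
    counts = filtered.counts
    logger.info(
        "preprocess: %d/%d records survive (normal=%d, abnormal=%d)",
        len(rows), len(manifest.records), counts[0], counts[1],
    )
    return survivors, filtered


def preprocess_recordings(
    recs: list[AudioRecording], cfg: PreprocessConfig = PreprocessConfig()
) -> list[AudioRecording]:
    """In-memory variant of the pipeline; discarded recordings are dropped."""
    out = []
    for rec in recs:
        processed = preprocess_recording(rec, cfg)
        if processed is not DISCARD:
            out.append(processed)
    return out
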