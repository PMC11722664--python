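"""Single-channel EEG cleaning and segmentation.

The chain mirrors standard scalp-EEG practice for a C3 (left motor
cortex) channel sampled at 1000 Hz: zero-phase high-pass to remove
baseline drift, an adaptive least-mean-squares (LMS) canceller locked to
the 50 Hz mains frequency, division of the hold interval into 5-s
non-overlapping segments, peak-amplitude artifact rejection, and a
zero-phase 8-12 Hz band-pass to isolate the alpha rhythm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "SegmentSet",
    "highpass",
    "adaptive_notch_50",
    "bandpass_alpha",
    "segment",
    "reject_artifacts",
    "crop",
]


@dataclass(frozen=True)
class EEGRecording:
    """Single-channel EEG trace (µV) with study metadata.

    ``annotations`` is a list of ``(start_s, end_s, label)`` intervals;
    the synthetic generator uses it to mark injected artifacts.
    """

    samples: np.ndarray
    fs: float = 1000.0
    subject_id: str = "S1"
    grip_level: int = 20
    trial_index: int = 0
    annotations: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EEGRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class SegmentSet:
    """Contiguous fixed-length windows of a recording.

    ``segments`` has shape (n_segments, samples_per_segment); rejected
    segments stay in the array (for audit) and are flagged false in
    ``kept_mask``.
    """

    segments: np.ndarray
    segment_length_s: float
    fs: float
    kept_mask: np.ndarray
    start_s: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def kept(self) -> np.ndarray:
        return self.segments[self.kept_mask]


def highpass(rec: EEGRecording, cutoff: float = 0.5, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth high-pass removing DC and baseline drift."""
    if not 0 < cutoff < rec.fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2), got {cutoff!r}")
    sos = sps.butter(order, cutoff, btype="highpass", fs=rec.fs, output="sos")
    return rec.with_samples(sps.sosfiltfilt(sos, rec.samples))


@njit(cache=True)
def _lms_notch(x, ref_sin, ref_cos, mu):
    n = x.size
    out = np.empty(n)
    w_s = 0.0
    w_c = 0.0
    for i in range(n):
        est = w_s * ref_sin[i] + w_c * ref_cos[i]
        e = x[i] - est
        out[i] = e
        w_s += 2.0 * mu * e * ref_sin[i]
        w_c += 2.0 * mu * e * ref_cos[i]
    return out, w_s, w_c


def adaptive_notch_50(rec: EEGRecording, adaptation_rate: float = 0.005,
                      line_freq: float = 50.0) -> EEGRecording:
    """LMS adaptive canceller for mains interference.

    A quadrature sine/cosine pair at the line frequency serves as the
    reference; two weights adapt by stochastic gradient descent so the
    canceller behaves as a narrow notch (bandwidth ~ mu*fs/pi Hz) that
    tracks slow amplitude/phase changes of the line component while
    leaving the rest of the spectrum essentially untouched.

    Raises
    ------
    RuntimeError
        If the weights diverge (try a smaller ``adaptation_rate``).
    """
    if rec.fs <= 2 * line_freq:
        raise ValueError("sampling frequency too low to cancel the line frequency")
    if adaptation_rate <= 0:
        raise ValueError("adaptation_rate must be > 0")
    t = np.arange(rec.samples.size) / rec.fs
    ref_sin = np.sin(2 * np.pi * line_freq * t)
    ref_cos = np.cos(2 * np.pi * line_freq * t)
    out, w_s, w_c = _lms_notch(
        np.ascontiguousarray(rec.samples), ref_sin, ref_cos, adaptation_rate
    )
    if not (np.isfinite(w_s) and np.isfinite(w_c) and np.all(np.isfinite(out))):
        raise RuntimeError(
            "LMS canceller diverged; reduce adaptation_rate "
            f"(current {adaptation_rate})"
        )
    return rec.with_samples(out)


def bandpass_alpha(rec: EEGRecording, lo: float = 8.0, hi: float = 12.0,
                   order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass isolating the alpha rhythm."""
    if rec.fs < 100:
        raise ValueError("fs must be >= 100 Hz for alpha extraction")
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_samples(sps.sosfiltfilt(sos, rec.samples))


def crop(rec: EEGRecording, start_s: float, end_s: float) -> EEGRecording:
    """Restrict a recording to the analysis window [start_s, end_s)."""
    if not 0 <= start_s < end_s <= rec.duration + 1e-9:
        raise ValueError(f"invalid window [{start_s}, {end_s}] for {rec.duration} s")
    i0, i1 = round(start_s * rec.fs), round(end_s * rec.fs)
    shifted = tuple(
        (a - start_s, b - start_s, lab)
        for (a, b, lab) in rec.annotations
        if b > start_s and a < end_s
    )
    return replace(rec, samples=rec.samples[i0:i1], annotations=shifted)


def segment(rec: EEGRecording, seg_len_s: float = 5.0) -> SegmentSet:
    """Divide a recording into non-overlapping fixed-length segments.

    Yields floor(duration / seg_len_s) contiguous segments; any
    remainder at the end is discarded.
    """
    seg_samples = round(seg_len_s * rec.fs)
    n_seg = rec.samples.size // seg_samples
    if n_seg < 1:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is shorter than one "
            f"{seg_len_s} s segment"
        )
    data = rec.samples[: n_seg * seg_samples].reshape(n_seg, seg_samples)
    return SegmentSet(
        segments=data,
        segment_length_s=seg_len_s,
        fs=rec.fs,
        kept_mask=np.ones(n_seg, dtype=bool),
        start_s=np.arange(n_seg) * seg_len_s,
    )


def reject_artifacts(segs: SegmentSet, amplitude_limit: float = 100.0) -> SegmentSet:
    """Flag segments whose peak absolute amplitude exceeds the limit.

    The conventional scalp-EEG bound of 100 µV peak is the default; the
    amplitude should be assessed after drift removal.  All segments are
    retained in the returned set for audit; only ``kept_mask`` changes.
    """
    if amplitude_limit <= 0:
        raise ValueError("amplitude_limit must be > 0")
    peaks = np.max(np.abs(segs.segments), axis=1)
    kept = segs.kept_mask & (peaks <= amplitude_limit)
    if not np.any(kept):
        warnings.warn(
            "all segments rejected; analysis set is empty", stacklevel=2
        )
    return replace(segs, kept_mask=kept)
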