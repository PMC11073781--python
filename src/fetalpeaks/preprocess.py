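"""Preprocessing: filtering, standardization, framing, and frame labeling.

Turns abdominal records plus fetal R-peak annotations into model-ready
labeled frame sets.  A frame is a contiguous, non-overlapping 65-ms window
of all 12 channels; it is labeled Class 1 when a fetal R-peak annotation
falls inside it (the fetal R-peak labeling, FRPL, scheme), Class 0
otherwise.  Class weights for the imbalanced two-class problem follow
``w_c = n_s / (n_c * n_s_c)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .sigsim import AbdominalRecord

__all__ = [
    "StandardizationParams",
    "FrameSet",
    "bandpass_notch",
    "fit_standardizer",
    "apply_standardizer",
    "segment",
    "frpl_label",
    "make_frameset",
    "class_weights",
]

logger = logging.getLogger(__name__)

FRAME_MS_DEFAULT = 65.0


class PreprocessError(ValueError):
    pass


class DegenerateChannelError(PreprocessError):
    """A channel with zero variance cannot be standardized."""


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass_notch(
    record: AbdominalRecord,
    low: float = 0.05,
    high: float = 100.0,
    notch: float = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> AbdominalRecord:
    """Zero-phase 0.05-100 Hz bandpass followed by a powerline notch.

    Butterworth bandpass applied forward-backward (``sosfiltfilt``) per
    channel, then an IIR notch at 50 or 60 Hz, also zero-phase.
    """
    fs = record.fs
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise PreprocessError(f"invalid band edges ({low}, {high}) at fs={fs}")
    if not 0 < notch < nyq:
        raise PreprocessError(f"notch {notch} Hz outside (0, {nyq})")
    # The 0.05 Hz corner sits 4 decades below Nyquist: a combined bandpass
    # design is ill-conditioned and the highpass edge transient would leak
    # past the notch, so highpass and lowpass are applied separately and the
    # highpass uses Gustafsson initial conditions to suppress edge effects.
    b_hp, a_hp = sps.butter(max(1, order // 2), low, btype="highpass", fs=fs)
    sos_lp = sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    b_n, a_n = sps.iirnotch(notch, notch_q, fs=fs)
    out = np.empty_like(record.signal, dtype=float)
    for ch in range(record.n_channels):
        x = sps.filtfilt(b_hp, a_hp, record.signal[ch], method="gust")
        x = sps.sosfiltfilt(sos_lp, x)
        out[ch] = sps.filtfilt(b_n, a_n, x)
    return AbdominalRecord(signal=out, fs=fs, subject_id=record.subject_id,
                           units=record.units, meta=dict(record.meta))


# ---------------------------------------------------------------------------
# Standardization (z-score per channel, training statistics only)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationParams:
    """Per-channel mean and SD, estimated on training records only."""

    mean: np.ndarray   # (n_channels,)
    sd: np.ndarray     # (n_channels,)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd) <= 0):
            bad = int(np.argmin(self.sd))
            raise DegenerateChannelError(
                f"channel {bad} has non-positive SD; cannot standardize")


def fit_standardizer(records: list[AbdominalRecord]) -> StandardizationParams:
    """Pool samples across the training records; per-channel mean and SD."""
    if not records:
        raise PreprocessError("training set is empty")
    pooled = np.concatenate([r.signal for r in records], axis=1)
    sd = pooled.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateChannelError(
            f"channel {bad} is constant in the training pool")
    return StandardizationParams(mean=pooled.mean(axis=1), sd=sd)


def apply_standardizer(params: StandardizationParams,
                       record: AbdominalRecord) -> AbdominalRecord:
    """z = (X - mu) / sigma, elementwise per channel."""
    z = (record.signal - params.mean[:, None]) / params.sd[:, None]
    return AbdominalRecord(signal=z, fs=record.fs, subject_id=record.subject_id,
                           units="z", meta=dict(record.meta))


# ---------------------------------------------------------------------------
# Framing and FRPL labels
# ---------------------------------------------------------------------------

def frame_length(fs: float, frame_ms: float = FRAME_MS_DEFAULT) -> int:
    return int(round(fs * frame_ms / 1000.0))


def segment(record: AbdominalRecord, frame_ms: float = FRAME_MS_DEFAULT
            ) -> tuple[np.ndarray, np.ndarray]:
    """Split a record into contiguous non-overlapping frames.

    Returns ``(frames, starts)`` where frames has shape
    ``(n_frames, frame_len, n_channels)``; the trailing remainder shorter
    than one frame is dropped.
    """
    flen = frame_length(record.fs, frame_ms)
    n = record.n_samples
    n_frames = n // flen
    if n_frames == 0:
        raise PreprocessError(
            f"record of {n} samples shorter than one {flen}-sample frame")
    trimmed = record.signal[:, : n_frames * flen]
    # (ch, nf, flen) -> (nf, flen, ch)
    frames = trimmed.reshape(record.n_channels, n_frames, flen)
    frames = np.transpose(frames, (1, 2, 0))
    starts = np.arange(n_frames, dtype=np.int64) * flen
    return np.ascontiguousarray(frames), starts


def frpl_label(starts: np.ndarray, frame_len: int,
               peaks: np.ndarray) -> np.ndarray:
    """Binary frame labels: 1 iff a peak lies in [start, start + frame_len)."""
    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size > 1 and not np.all(np.diff(peaks) > 0):
        logger.warning("peak annotations not sorted; sorting internally")
        peaks = np.unique(peaks)
    starts = np.asarray(starts, dtype=np.int64)
    labels = np.zeros(len(starts), dtype=np.int64)
    if peaks.size and len(starts):
        rel = peaks - starts[0]
        idx = rel // frame_len
        idx = idx[(rel >= 0) & (idx < len(starts))]
        labels[idx] = 1
    return labels


@dataclass
class FrameSet:
    """Labeled frames from one subject record."""

    frames: np.ndarray          # (n_frames, frame_len, n_channels)
    labels: np.ndarray          # (n_frames,) in {0, 1}
    starts: np.ndarray          # (n_frames,) start sample of each frame
    subject_id: str
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.labels) == len(self.starts)):
            raise PreprocessError("frames/labels/starts length mismatch")

    @property
    def frame_len(self) -> int:
        return self.frames.shape[1]

    def __len__(self) -> int:
        return len(self.frames)

    def save(self, path) -> None:
        np.savez_compressed(path, frames=self.frames, labels=self.labels,
                            starts=self.starts, fs=self.fs,
                            subject_id=self.subject_id)

    @classmethod
    def load(cls, path) -> "FrameSet":
        z = np.load(path, allow_pickle=False)
        return cls(frames=z["frames"], labels=z["labels"], starts=z["starts"],
                   subject_id=str(z["subject_id"]), fs=float(z["fs"]))


def make_frameset(record: AbdominalRecord, peaks: np.ndarray,
                  frame_ms: float = FRAME_MS_DEFAULT) -> FrameSet:
    """Segment a (filtered, standardized) record and attach FRPL labels."""
    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size and (peaks.min() < 0 or peaks.max() >= record.n_samples):
        raise PreprocessError("peak annotation outside record bounds")
    frames, starts = segment(record, frame_ms)
    labels = frpl_label(starts, frames.shape[1], peaks)
    return FrameSet(frames=frames, labels=labels, starts=starts,
                    subject_id=record.subject_id, fs=record.fs)


# ---------------------------------------------------------------------------
# Class weights
# ---------------------------------------------------------------------------

def class_weights(labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency class weights ``w_c = n_s / (n_c * n_s_c)``.

    ``n_s`` is the number of labeled frames, ``n_c = 2`` the number of
    classes and ``n_s_c`` the per-class count.  Balanced labels give
    (1, 1); the rarer class is up-weighted.
    """
    labels = np.asarray(labels)
    ns = labels.size
    ns1 = int(np.count_nonzero(labels == 1))
    ns0 = ns - ns1
    if ns0 == 0 or ns1 == 0:
        raise PreprocessError(
            "both classes must be present to compute class weights")
    n_classes = 2
    return ns / (n_classes * ns0), ns / (n_classes * ns1)
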