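"""Detection post-processing (FECGPP).

Refines raw frame-level BiLSTM detections into a physiologically plausible
fetal R-peak event sequence.  Two mechanisms:

* a refractory pass removing the lower-confidence event of any pair closer
  than a minimum R-R interval (default 250 ms, a 240-bpm fetal ceiling);
* a gap-fill pass promoting the best unused frame inside an inter-event gap
  larger than ``gap_factor`` times the running median R-R interval,
  recovering single missed beats.

Event times live at frame centers — detection operates at frame resolution,
so half a frame (~32 ms) is the intrinsic localization precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DetectionTrack", "PeakEvents", "merge_runs", "fecgpp",
           "events_to_frame_labels", "FecgppConfig"]

logger = logging.getLogger(__name__)


@dataclass
class DetectionTrack:
    """Raw per-frame classifier output for one record."""

    posteriors: np.ndarray      # (n_frames,) Class-1 posterior
    labels: np.ndarray          # (n_frames,) hard labels {0, 1}
    starts: np.ndarray          # (n_frames,) frame start samples
    frame_len: int
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.posteriors) == len(self.labels) == len(self.starts)):
            raise ValueError("posterior/label/start length mismatch")


@dataclass
class PeakEvents:
    """Refined peak events: strictly increasing sample indices."""

    samples: np.ndarray         # (n_events,) event sample index
    confidence: np.ndarray      # (n_events,) posterior of the source frame
    frame_index: np.ndarray     # (n_events,) source frame of each event
    fs: float

    def __post_init__(self) -> None:
        if self.samples.size > 1 and not np.all(np.diff(self.samples) > 0):
            raise ValueError("event samples must be strictly increasing")


@dataclass(frozen=True)
class FecgppConfig:
    rr_min_ms: float = 250.0
    gap_factor: float = 1.8
    short_factor: float = 0.55  # R-R below this multiple of the running
    #                             median marks a split beat / false positive
    promote_floor: float = 0.2
    median_window: int = 9        # gap-fill reference window (intervals)
    short_median_window: int = 21  # wider, so clustered false positives
    #                                cannot drag their own reference down


def _frame_center(track: DetectionTrack, idx: int) -> int:
    return int(track.starts[idx] + track.frame_len // 2)


def merge_runs(track: DetectionTrack) -> PeakEvents:
    """Collapse each maximal run of consecutive Class-1 frames to one event.

    The event sits at the center sample of the run's maximum-posterior frame
    and inherits that posterior as its confidence.
    """
    lab = np.asarray(track.labels, dtype=np.int64)
    samples, conf, frames = [], [], []
    i = 0
    n = len(lab)
    while i < n:
        if lab[i] == 1:
            j = i
            while j + 1 < n and lab[j + 1] == 1:
                j += 1
            k = i + int(np.argmax(track.posteriors[i:j + 1]))
            samples.append(_frame_center(track, k))
            conf.append(float(track.posteriors[k]))
            frames.append(k)
            i = j + 1
        else:
            i += 1
    return PeakEvents(samples=np.asarray(samples, dtype=np.int64),
                      confidence=np.asarray(conf),
                      frame_index=np.asarray(frames, dtype=np.int64),
                      fs=track.fs)


def _refractory_pass(samples, conf, frames, rr_min: float):
    """Greedy removal: while any pair is closer than rr_min, drop the
    lower-confidence member of the closest offending pair."""
    s = list(samples)
    c = list(conf)
    f = list(frames)
    changed = True
    while changed and len(s) > 1:
        changed = False
        gaps = np.diff(s)
        bad = np.flatnonzero(gaps < rr_min)
        if bad.size:
            i = int(bad[np.argmin(gaps[bad])])
            drop = i if c[i] < c[i + 1] else i + 1
            del s[drop], c[drop], f[drop]
            changed = True
    return s, c, f


def _running_median_rr(s: list[int], window: int) -> np.ndarray:
    """Median of up to `window` intervals centered on each interval.

    A centered window keeps the estimate robust at the record edges, where
    a trailing window would let early false positives set their own
    reference rhythm."""
    rr = np.diff(s)
    med = np.empty(len(rr))
    half = window // 2
    for i in range(len(rr)):
        lo = max(0, i - half)
        med[i] = np.median(rr[lo:i + half + 1])
    return med


def _short_interval_pass(s, c, f, cfg: FecgppConfig):
    """Rhythm-adaptive false-positive suppression: while an interval is
    shorter than ``short_factor`` times the running median R-R, delete the
    lower-confidence member of the worst offending pair.  Complements the
    absolute refractory floor, which cannot catch split beats in slow
    rhythms."""
    while len(s) > 2:
        rr = np.diff(s).astype(float)
        med = _running_median_rr(s, cfg.short_median_window)
        ratio = rr / np.maximum(med, 1.0)
        i = int(np.argmin(ratio))
        if ratio[i] >= cfg.short_factor:
            break
        drop = i if c[i] < c[i + 1] else i + 1
        del s[drop], c[drop], f[drop]
    return s, c, f


def _gap_fill_pass(s, c, f, track: DetectionTrack, cfg: FecgppConfig,
                   rr_min: float):
    """Insert the best unused frame into every oversized inter-event gap."""
    if len(s) < 3:
        return s, c, f
    used = set(f)
    med = _running_median_rr(s, cfg.median_window)
    out_s, out_c, out_f = [s[0]], [c[0]], [f[0]]
    for i in range(len(s) - 1):
        gap = s[i + 1] - s[i]
        if gap > cfg.gap_factor * med[i]:
            lo_frame = f[i] + 1
            hi_frame = f[i + 1]
            cand = [k for k in range(lo_frame, hi_frame)
                    if k not in used
                    and track.posteriors[k] >= cfg.promote_floor]
            # inserted events must respect both the refractory floor and the
            # short-interval rule on each side, or a second pass would
            # delete them again
            floor = max(rr_min, cfg.short_factor * med[i])
            cand = [k for k in cand
                    if _frame_center(track, k) - s[i] >= floor
                    and s[i + 1] - _frame_center(track, k) >= floor]
            if cand:
                k = max(cand, key=lambda k: track.posteriors[k])
                out_s.append(_frame_center(track, k))
                out_c.append(float(track.posteriors[k]))
                out_f.append(k)
                used.add(k)
        out_s.append(s[i + 1])
        out_c.append(c[i + 1])
        out_f.append(f[i + 1])
    return out_s, out_c, out_f


def fecgpp(events: PeakEvents, track: DetectionTrack,
           config: FecgppConfig | None = None) -> PeakEvents:
    """One refractory pass then one gap-fill pass over candidate events."""
    cfg = config or FecgppConfig()
    if len(events.samples) < 2:
        logger.info("fewer than 2 events; FECGPP is a no-op")
        return events
    rr_min = cfg.rr_min_ms * track.fs / 1000.0
    s, c, f = _refractory_pass(list(events.samples), list(events.confidence),
                               list(events.frame_index), rr_min)
    s, c, f = _short_interval_pass(s, c, f, cfg)
    # iterate the gap-fill to its fixed point so gaps spanning several
    # missed beats are fully recovered and the whole operator is idempotent
    for _ in range(len(track.labels)):
        s2, c2, f2 = _gap_fill_pass(s, c, f, track, cfg, rr_min)
        if len(s2) == len(s):
            break
        s, c, f = s2, c2, f2
    else:  # pragma: no cover - defensive
        s, c, f = s2, c2, f2
    return PeakEvents(samples=np.asarray(s, dtype=np.int64),
                      confidence=np.asarray(c),
                      frame_index=np.asarray(f, dtype=np.int64),
                      fs=track.fs)


def events_to_frame_labels(events: PeakEvents, n_frames: int) -> np.ndarray:
    """Frame-level binary labels implied by a refined event sequence."""
    lab = np.zeros(n_frames, dtype=np.int64)
    idx = events.frame_index[(events.frame_index >= 0)
                             & (events.frame_index < n_frames)]
    lab[idx] = 1
    return lab
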