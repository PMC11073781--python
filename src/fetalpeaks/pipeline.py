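"""End-to-end pipeline: simulate -> preprocess -> train -> detect ->
post-process -> heart rate -> evaluate.

A single global seed fans out deterministically to per-stage seeds
(``stage_seed = (seed * 1009 + stage_index) mod 2^31 - 1``) so each stage is
independently reproducible; the run manifest records the configuration,
the derived seeds, and a checksum per artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from . import heartrate as hr
from . import postprocess as pp
from .detector import (BiLSTMDetector, DetectorConfig, TrainSchedule,
                       build_network, predict, train)
from .preprocess import (FrameSet, apply_standardizer, bandpass_notch,
                         class_weights, fit_standardizer, make_frameset)
from .sigsim import SimConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "run_experiment",
            "prepare_framesets", "PipelineStageError"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "preprocess", "train", "detect", "postprocess",
           "heartrate", "evaluate")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1009 + _STAGES.index(stage)) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    """Nested configuration of every stage; YAML round-trippable."""

    n_subjects: int = 6
    held_out: int = -1                      # index of the test subject
    duration_s: float = 60.0
    sampling_rate: float = 1000.0
    fetal_ratio: float = 0.3
    noise_baseline: float = 0.1
    noise_powerline: float = 0.05
    noise_white: float = 0.1
    powerline_freq: float = 50.0
    bandpass: tuple[float, float] = (0.05, 100.0)
    frame_ms: float = 65.0
    hidden_sizes: tuple[int, ...] = (64, 32, 16)
    dropout_rates: tuple[float, ...] = (0.2, 0.2)
    epochs: int = 15
    initial_lr: float = 2e-3
    batch_size: int = 32
    n_models: int = 3            # ensemble size; posteriors are averaged
    rr_min_ms: float = 250.0
    gap_factor: float = 1.8
    promote_floor: float = 0.2
    sdrom_thresholds: tuple[float, float] = (8.0, 20.0)
    smooth_alpha: float = 0.3
    hr_window_s: float = 10.0
    seed: int = 0
    out_dir: str = "fetalpeaks_run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = data[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            sampling_rate=self.sampling_rate, duration=self.duration_s,
            fetal_to_maternal_amplitude_ratio=self.fetal_ratio,
            noise_baseline=self.noise_baseline,
            noise_powerline=self.noise_powerline,
            noise_white=self.noise_white,
            powerline_freq=self.powerline_freq,
        )


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def prepare_framesets(cohort, cfg: PipelineConfig, train_ids: set[str]
                      ) -> list[FrameSet]:
    """Filter, standardize (training statistics only) and frame a cohort."""
    filtered = []
    for rec, gt in cohort:
        filtered.append((bandpass_notch(rec, low=cfg.bandpass[0],
                                        high=cfg.bandpass[1],
                                        notch=cfg.powerline_freq), gt))
    params = fit_standardizer([rec for rec, _ in filtered
                               if rec.subject_id in train_ids])
    out = []
    for rec, gt in filtered:
        z = apply_standardizer(params, rec)
        out.append(make_frameset(z, gt.fetal_peak_samples, cfg.frame_ms))
    return out


def _detect_track(models, fs: FrameSet,
                  threshold: float = 0.5) -> pp.DetectionTrack:
    """Average Class-1 posteriors over one or more models."""
    if isinstance(models, BiLSTMDetector):
        models = [models]
    probs = np.mean([predict(m, fs)[0] for m in models], axis=0)
    return pp.DetectionTrack(posteriors=probs,
                             labels=(probs >= threshold).astype(np.int64),
                             starts=fs.starts, frame_len=fs.frame_len,
                             fs=fs.fs)


def _hr_series(peaks: np.ndarray, fs: float, cfg: PipelineConfig,
               duration: float) -> hr.HeartRateSeries:
    return hr.windowed_hr(peaks, fs, window_s=cfg.hr_window_s,
                          duration_s=duration)


# ---------------------------------------------------------------------------
# Held-out-subject experiment (the core evaluation run)
# ---------------------------------------------------------------------------

def run_experiment(cfg: PipelineConfig | None = None, verbose: bool = False
                   ) -> dict:
    """Simulate a cohort, train on all but one subject, evaluate on the rest.

    Returns a dict with raw and post-processed frame metrics, beat-level
    matching, and heart-rate recovery figures for the held-out subject.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.time()
    cohort = generate_cohort(cfg.n_subjects, cfg.sim_config(),
                             seed=stage_seed(cfg.seed, "simulate"))
    held = cfg.held_out % cfg.n_subjects
    test_rec, test_gt = cohort[held]
    train_ids = {rec.subject_id for i, (rec, _) in enumerate(cohort)
                 if i != held}

    framesets = prepare_framesets(cohort, cfg, train_ids)
    train_sets = [fs for i, fs in enumerate(framesets) if i != held]
    test_set = framesets[held]

    y_train = np.concatenate([fs.labels for fs in train_sets])
    w0, w1 = class_weights(y_train)
    # small ensemble: identical data, different init/shuffle/dropout seeds;
    # averaging the posteriors damps the run-to-run variance of short
    # training schedules
    models, histories = [], []
    for k in range(max(1, cfg.n_models)):
        member_seed = (stage_seed(cfg.seed, "train") + 7919 * k) % (2**31 - 1)
        model = build_network(
            DetectorConfig(bilstm_hidden_sizes=tuple(cfg.hidden_sizes),
                           dropout_rates=tuple(cfg.dropout_rates)),
            rng_seed=member_seed)
        schedule = TrainSchedule(epochs=cfg.epochs, initial_lr=cfg.initial_lr,
                                 batch_size=cfg.batch_size,
                                 rng_seed=member_seed,
                                 class_weights=(w0, w1))
        histories.append(train(model, train_sets, schedule,
                               log_every=5 if verbose else 0))
        models.append(model)
    history = histories[0]

    track = _detect_track(models, test_set)
    raw = ev.confusion_metrics(test_set.labels, track.labels)

    events = pp.fecgpp(pp.merge_runs(track), track,
                       pp.FecgppConfig(rr_min_ms=cfg.rr_min_ms,
                                       gap_factor=cfg.gap_factor,
                                       promote_floor=cfg.promote_floor))
    post_labels = pp.events_to_frame_labels(events, len(test_set))
    post = ev.confusion_metrics(test_set.labels, post_labels)
    beat = ev.match_peaks(events.samples, test_gt.fetal_peak_samples,
                          test_set.fs)

    duration = test_rec.n_samples / test_rec.fs
    hr_true = _hr_series(test_gt.fetal_peak_samples, test_set.fs, cfg,
                         duration)
    result: dict = {
        "config": asdict(cfg),
        "class_weights": (w0, w1),
        "history": history,
        "raw": raw.as_dict(),
        "post": post.as_dict(),
        "beat": beat,
        "n_events": int(len(events.samples)),
        "n_true_peaks": int(len(test_gt.fetal_peak_samples)),
        "wall_time_s": time.time() - t0,
    }
    if len(events.samples) >= 2:
        hr_raw = _hr_series(events.samples, test_set.fs, cfg, duration)
        hr_enh = hr.fhre(hr_raw, thresholds=tuple(cfg.sdrom_thresholds),
                         alpha=cfg.smooth_alpha)
        both = hr_true.defined() & hr_enh.defined()
        mae = float(np.mean(np.abs(hr_enh.hr[both] - hr_true.hr[both]))) \
            if both.any() else float("nan")
        result["hr"] = {
            "true_bpm": hr_true.hr.tolist(),
            "raw_bpm": hr_raw.hr.tolist(),
            "fhre_bpm": hr_enh.hr.tolist(),
            "mae_bpm": mae,
            "n_windows": int(both.sum()),
        }
        result["_events"] = events
        result["_hr_true"] = hr_true
        result["_hr_enh"] = hr_enh
    result["_track"] = track
    result["_model"] = models[0]
    return result


# ---------------------------------------------------------------------------
# Full artifact-producing pipeline
# ---------------------------------------------------------------------------

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write artifacts + manifest under
    ``cfg.out_dir``.  Any stage failure raises PipelineStageError naming
    the stage."""
    from .sigsim import write_cohort

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "artifacts": {}}

    def run_stage(name, fn):
        t = time.time()
        try:
            value = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineStageError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "ok", "wall_time_s": round(time.time() - t, 3),
            "seed": stage_seed(cfg.seed, name) if name in _STAGES else None,
        }
        logger.info("stage %s done in %.2fs", name,
                    manifest["stages"][name]["wall_time_s"])
        return value

    cohort = run_stage("simulate", lambda: generate_cohort(
        cfg.n_subjects, cfg.sim_config(),
        seed=stage_seed(cfg.seed, "simulate")))
    run_stage("write_cohort", lambda: write_cohort(cohort, out / "cohort"))

    result = run_stage("experiment", lambda: run_experiment(cfg))

    # persist artifacts
    det_csv = out / "detections.csv"
    peaks_csv = out / "peaks.csv"
    hr_csv = out / "hr.csv"
    report_json = out / "report.json"

    events = result.pop("_events", None)
    hr_true = result.pop("_hr_true", None)
    hr_enh = result.pop("_hr_enh", None)
    track = result.pop("_track", None)
    model = result.pop("_model", None)
    if model is not None:
        model.save(out / "model.ckpt")
        manifest["artifacts"]["model.ckpt"] = _checksum(out / "model.ckpt")
    if track is not None:
        with det_csv.open("w") as fh:
            fh.write("frame,start_sample,posterior,label\n")
            for i, (s, p, l) in enumerate(zip(track.starts, track.posteriors,
                                              track.labels)):
                fh.write(f"{i},{int(s)},{p:.6f},{int(l)}\n")
    if events is not None:
        with peaks_csv.open("w") as fh:
            fh.write("sample,time_s,confidence\n")
            for s, c in zip(events.samples, events.confidence):
                fh.write(f"{int(s)},{s / events.fs:.4f},{c:.4f}\n")
    if hr_true is not None and hr_enh is not None:
        with hr_csv.open("w") as fh:
            fh.write("t_start_s,t_end_s,hr_true_bpm,hr_fhre_bpm\n")
            for t0, t1, a, b in zip(hr_true.t_start, hr_true.t_end,
                                    hr_true.hr, hr_enh.hr):
                fh.write(f"{t0:.1f},{t1:.1f},{a:.3f},{b:.3f}\n")
    report_json.write_text(json.dumps(
        {k: v for k, v in result.items() if not k.startswith("_")}, indent=2))
    for p in (det_csv, peaks_csv, hr_csv, report_json):
        if p.exists():
            manifest["artifacts"][p.name] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
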