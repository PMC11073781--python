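"""Synthetic maternal-fetal abdominal ECG simulator.

Generates 12-channel abdominal composite records — a large, slow maternal
ECG plus a small, fast fetal ECG mixed into each lead with per-lead gains,
on top of baseline wander, powerline interference and broadband noise —
together with ground-truth R-peak sample indices for both rhythms.

The beat model is a Gaussian-sum PQRST template evaluated over a per-beat
phase variable: each of the five waves contributes
``a_k * exp(-(theta - theta_k)^2 / (2 * b_k^2))`` where ``theta`` ramps
linearly from -pi to pi across one R-R interval, with the R wave centred at
phase 0.  R-R intervals are i.i.d. truncated-normal draws, so the rhythm is
a renewal process with controllable mean heart rate and variability.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "WaveParams",
    "BeatMorphology",
    "SimConfig",
    "GroundTruth",
    "AbdominalRecord",
    "MATERNAL_MORPHOLOGY",
    "FETAL_MORPHOLOGY",
    "synth_beat_train",
    "mix_abdominal",
    "simulate_record",
    "generate_cohort",
    "write_cohort",
    "write_record",
    "write_annotations",
    "read_record",
    "read_annotations",
]


class SimConfigError(ValueError):
    """Raised for invalid simulator configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveParams:
    """One wave of the PQRST complex: Gaussian bump on the beat phase axis."""

    amplitude: float          # dimensionless, relative to R = 1
    width: float              # Gaussian sigma, radians of beat phase
    phase: float              # centre, radians (R wave at 0)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise SimConfigError(f"wave width must be positive, got {self.width}")


@dataclass(frozen=True)
class BeatMorphology:
    """Gaussian-sum PQRST morphology; R must dominate in magnitude."""

    P: WaveParams
    Q: WaveParams
    R: WaveParams
    S: WaveParams
    T: WaveParams

    def __post_init__(self) -> None:
        waves = {"P": self.P, "Q": self.Q, "R": self.R, "S": self.S, "T": self.T}
        amps = {n: abs(w.amplitude) for n, w in waves.items()}
        if any(a > 0 for a in amps.values()):
            if self.R.amplitude <= 0:
                raise SimConfigError("R amplitude must be strictly positive")
            if any(amps[n] >= amps["R"] for n in "PQST"):
                raise SimConfigError("R amplitude must dominate all other waves")

    def waves(self) -> list[WaveParams]:
        return [self.P, self.Q, self.R, self.S, self.T]

    @classmethod
    def zero(cls) -> "BeatMorphology":
        z = WaveParams(0.0, 0.1, 0.0)
        return cls(P=z, Q=z, R=WaveParams(0.0, 0.1, 0.0), S=z, T=z)


# Canonical adult template (McSharry-style positions); the fetal template is
# narrower in phase because the fetal QRS occupies a larger fraction of its
# shorter beat.
MATERNAL_MORPHOLOGY = BeatMorphology(
    P=WaveParams(0.12, 0.25, -np.pi / 3),
    Q=WaveParams(-0.10, 0.10, -np.pi / 12),
    R=WaveParams(1.00, 0.10, 0.0),
    S=WaveParams(-0.12, 0.10, np.pi / 12),
    T=WaveParams(0.30, 0.40, np.pi / 2),
)

FETAL_MORPHOLOGY = BeatMorphology(
    P=WaveParams(0.10, 0.22, -np.pi / 3),
    Q=WaveParams(-0.08, 0.09, -np.pi / 14),
    R=WaveParams(1.00, 0.09, 0.0),
    S=WaveParams(-0.10, 0.09, np.pi / 14),
    T=WaveParams(0.25, 0.35, np.pi / 2),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic abdominal recording."""

    sampling_rate: float = 1000.0          # Hz
    duration: float = 60.0                 # s
    maternal_hr_mean: float = 80.0         # bpm
    maternal_hr_sd: float = 3.0            # bpm
    fetal_hr_mean: float = 140.0           # bpm
    fetal_hr_sd: float = 5.0               # bpm
    fetal_to_maternal_amplitude_ratio: float = 0.3
    maternal_gain_range: tuple[float, float] = (0.5, 1.5)
    noise_baseline: float = 0.1            # RMS, signal units
    noise_powerline: float = 0.05          # RMS, signal units
    noise_white: float = 0.1               # RMS, signal units
    powerline_freq: float = 50.0           # Hz, 50 or 60
    quantization_bits: int = 16
    # +/- full-scale in signal units; unit-RMS sources make QRS peaks reach
    # ~7 units at the highest lead gains, so 10 leaves ADC headroom
    full_scale: float = 10.0
    n_channels: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SimConfigError("sampling_rate must be positive")
        if self.duration <= 0:
            raise SimConfigError("duration must be positive")
        for name, hr in (("maternal", self.maternal_hr_mean),
                         ("fetal", self.fetal_hr_mean)):
            if not 30.0 < hr < 300.0:
                raise SimConfigError(f"{name} HR mean {hr} outside (30, 300) bpm")
        r = self.fetal_to_maternal_amplitude_ratio
        if not 0.0 < r <= 1.0:
            raise SimConfigError(f"amplitude ratio {r} outside (0, 1]")
        if self.powerline_freq not in (50.0, 60.0):
            raise SimConfigError("powerline_freq must be 50 or 60 Hz")
        if self.quantization_bits < 2:
            raise SimConfigError("quantization_bits must be >= 2")


@dataclass
class GroundTruth:
    """Reference annotations carried alongside a simulated record."""

    fetal_peak_samples: np.ndarray      # strictly increasing ints
    maternal_peak_samples: np.ndarray
    fetal_source: np.ndarray            # clean unit-scale fetal trace
    maternal_source: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fetal_peak_samples", "maternal_peak_samples"):
            p = np.asarray(getattr(self, name), dtype=np.int64)
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, p)


@dataclass
class AbdominalRecord:
    """Multichannel abdominal signal: channels x samples."""

    signal: np.ndarray                  # (n_channels, n_samples)
    fs: float                           # Hz
    subject_id: str = "s00"
    units: str = "mV"
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]


# ---------------------------------------------------------------------------
# Beat-train synthesis
# ---------------------------------------------------------------------------

def _draw_rr_intervals(hr_mean: float, hr_sd: float, duration: float,
                       rng: np.random.Generator) -> np.ndarray:
    """i.i.d. truncated-normal R-R intervals covering at least `duration`."""
    rr_mean = 60.0 / hr_mean
    # delta-method: sd of RR from sd of HR
    rr_sd = 60.0 * hr_sd / hr_mean ** 2
    lo = max(0.2, rr_mean - 3.0 * rr_sd)
    hi = rr_mean + 3.0 * rr_sd
    out: list[float] = []
    total = 0.0
    while total < duration + rr_mean:
        if rr_sd == 0:
            rr = rr_mean
        else:
            rr = rng.normal(rr_mean, rr_sd)
            while not (lo <= rr <= hi):
                rr = rng.normal(rr_mean, rr_sd)
        out.append(rr)
        total += rr
    return np.asarray(out)


def synth_beat_train(
    hr_mean: float,
    hr_sd: float,
    morphology: BeatMorphology,
    fs: float,
    duration: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one clean single-channel beat train.

    Returns ``(trace, peak_samples)`` with ``len(trace) == round(fs*duration)``
    and one annotated peak per beat whose R time falls inside the record.
    Peaks sit at the sample of maximum R-wave amplitude (the scheduled R time
    when the morphology is flat).
    """
    if fs <= 0 or duration <= 0:
        raise SimConfigError("fs and duration must be positive")
    if duration * hr_mean / 60.0 < 1:
        raise SimConfigError("duration too short to hold one beat")
    rng = np.random.default_rng(rng)

    n = int(round(fs * duration))
    rr = _draw_rr_intervals(hr_mean, hr_sd, duration, rng)
    # first R half an interval in, so the record does not start mid-QRS
    r_times = 0.5 * rr[0] + np.concatenate(([0.0], np.cumsum(rr[:-1])))

    trace = np.zeros(n)
    peaks: list[int] = []
    t = np.arange(n) / fs
    r_amp = morphology.R.amplitude
    for j, r_t in enumerate(r_times):
        if r_t >= duration:
            break
        rr_j = rr[j]
        lo = max(0, int(np.floor((r_t - 0.5 * rr_j) * fs)))
        hi = min(n, int(np.ceil((r_t + 0.5 * rr_j) * fs)) + 1)
        if hi <= lo:
            continue
        theta = 2.0 * np.pi * (t[lo:hi] - r_t) / rr_j
        seg = np.zeros(hi - lo)
        for w in morphology.waves():
            if w.amplitude != 0.0:
                seg += w.amplitude * np.exp(-((theta - w.phase) ** 2)
                                            / (2.0 * w.width ** 2))
        trace[lo:hi] += seg
        sched = int(round(r_t * fs))
        if sched >= n:
            continue
        if r_amp > 0:
            # locate the realized R maximum on the sampled grid
            half_w = max(1, int(round(morphology.R.width * rr_j * fs
                                      / (2.0 * np.pi))) * 3)
            a = max(lo, sched - half_w)
            b = min(n, sched + half_w + 1)
            peak = a + int(np.argmax(trace[a:b]))
        else:
            peak = sched
        if not peaks or peak > peaks[-1]:
            peaks.append(peak)
    return trace, np.asarray(peaks, dtype=np.int64)


# ---------------------------------------------------------------------------
# Lead mixing
# ---------------------------------------------------------------------------

def _draw_lead_gains(cfg: SimConfig, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-lead (maternal, fetal) gains.

    Fetal gains are tied to the maternal gain of the same lead through the
    configured amplitude ratio (within +/-10% jitter) and carry a random
    sign, mimicking electrode-geometry polarity flips.  With unit-RMS
    sources this pins the per-channel fetal/maternal RMS ratio to the
    configured value.
    """
    lo, hi = cfg.maternal_gain_range
    g_m = rng.uniform(lo, hi, size=cfg.n_channels)
    jitter = rng.uniform(0.9, 1.1, size=cfg.n_channels)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_channels)
    g_f = signs * cfg.fetal_to_maternal_amplitude_ratio * g_m * jitter
    return g_m, g_f


def _quantize(x: np.ndarray, bits: int, full_scale: float) -> np.ndarray:
    step = 2.0 * full_scale / (2 ** bits)
    return np.clip(np.round(x / step) * step, -full_scale, full_scale - step)


def mix_abdominal(
    maternal: np.ndarray,
    fetal: np.ndarray,
    cfg: SimConfig,
    maternal_peaks: np.ndarray | None = None,
    fetal_peaks: np.ndarray | None = None,
) -> tuple[AbdominalRecord, GroundTruth]:
    """Mix two source traces into a 12-lead quantized composite.

    Each channel is ``g_m*maternal + g_f*fetal`` plus baseline wander,
    a powerline tone and white noise, quantized to the configured bit depth
    over +/-``full_scale``.  The mixing is strictly linear in the sources:
    for a fixed seed the gains and noise realization are identical, so
    ``mix(a, b) + mix(c, d) == mix(a+c, b+d)`` up to quantization.
    Amplitude conventions assume unit-RMS sources (see ``generate_cohort``).
    """
    maternal = np.asarray(maternal, dtype=float)
    fetal = np.asarray(fetal, dtype=float)
    if maternal.shape != fetal.shape:
        raise ValueError(
            f"source length mismatch: {maternal.shape} vs {fetal.shape}")
    n = maternal.size
    rng = np.random.default_rng(cfg.rng_seed)
    g_m, g_f = _draw_lead_gains(cfg, rng)

    t = np.arange(n) / cfg.sampling_rate
    sig = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        x = g_m[ch] * maternal + g_f[ch] * fetal
        if cfg.noise_baseline > 0:
            f_bw = rng.uniform(0.05, 0.45)
            phase = rng.uniform(0, 2 * np.pi)
            # sinusoid RMS is amp/sqrt(2)
            x = x + cfg.noise_baseline * np.sqrt(2.0) * np.sin(
                2 * np.pi * f_bw * t + phase)
        if cfg.noise_powerline > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x = x + cfg.noise_powerline * np.sqrt(2.0) * np.sin(
                2 * np.pi * cfg.powerline_freq * t + phase)
        if cfg.noise_white > 0:
            x = x + rng.normal(0.0, cfg.noise_white, size=n)
        sig[ch] = x
    sig = _quantize(sig, cfg.quantization_bits, cfg.full_scale)

    gt = GroundTruth(
        fetal_peak_samples=np.asarray([] if fetal_peaks is None else fetal_peaks,
                                      dtype=np.int64),
        maternal_peak_samples=np.asarray(
            [] if maternal_peaks is None else maternal_peaks, dtype=np.int64),
        fetal_source=fetal,
        maternal_source=maternal,
    )
    rec = AbdominalRecord(
        signal=sig, fs=cfg.sampling_rate, units="mV",
        meta={"gains_maternal": g_m.tolist(), "gains_fetal": g_f.tolist()},
    )
    return rec, gt


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = float(np.sqrt(np.mean(x ** 2)))
    return x / rms if rms > 0 else x


def simulate_record(cfg: SimConfig, subject_id: str = "s00"
                    ) -> tuple[AbdominalRecord, GroundTruth]:
    """Full single-subject simulation: two beat trains, normalized, mixed."""
    rng = np.random.default_rng(cfg.rng_seed)
    m_seed, f_seed = rng.integers(0, 2 ** 31 - 1, size=2)
    m_trace, m_peaks = synth_beat_train(
        cfg.maternal_hr_mean, cfg.maternal_hr_sd, MATERNAL_MORPHOLOGY,
        cfg.sampling_rate, cfg.duration, np.random.default_rng(int(m_seed)))
    f_trace, f_peaks = synth_beat_train(
        cfg.fetal_hr_mean, cfg.fetal_hr_sd, FETAL_MORPHOLOGY,
        cfg.sampling_rate, cfg.duration, np.random.default_rng(int(f_seed)))
    rec, gt = mix_abdominal(_unit_rms(m_trace), _unit_rms(f_trace), cfg,
                            maternal_peaks=m_peaks, fetal_peaks=f_peaks)
    rec.subject_id = subject_id
    return rec, gt


def generate_cohort(
    n_subjects: int,
    cfg: SimConfig | None = None,
    seed: int = 0,
    fetal_hr_range: tuple[float, float] = (110.0, 160.0),
    maternal_hr_range: tuple[float, float] = (60.0, 100.0),
) -> list[tuple[AbdominalRecord, GroundTruth]]:
    """Simulate a cohort with per-subject heart rates drawn from the given
    ranges; the same seed reproduces the cohort bit for bit."""
    if n_subjects < 1:
        raise SimConfigError("n_subjects must be >= 1")
    base = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        f_hr = rng.uniform(*fetal_hr_range)
        m_hr = rng.uniform(*maternal_hr_range)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        sub_cfg = replace(base, fetal_hr_mean=f_hr, maternal_hr_mean=m_hr,
                          rng_seed=sub_seed)
        rec, gt = simulate_record(sub_cfg, subject_id=f"s{i:02d}")
        rec.meta["fetal_hr_mean"] = f_hr
        rec.meta["maternal_hr_mean"] = m_hr
        cohort.append((rec, gt))
    return cohort


# ---------------------------------------------------------------------------
# On-disk formats: CSV signal + plain-text annotations + JSON manifest
# ---------------------------------------------------------------------------

def write_record(rec: AbdominalRecord, path: str | Path) -> None:
    """Write `time_s,ch01..ch12` CSV."""
    path = Path(path)
    header = ["time_s"] + [f"ch{c + 1:02d}" for c in range(rec.n_channels)]
    t = np.arange(rec.n_samples) / rec.fs
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for i in range(rec.n_samples):
            w.writerow([f"{t[i]:.6f}"] + [f"{v:.6f}" for v in rec.signal[:, i]])


def read_record(path: str | Path, fs: float | None = None,
                subject_id: str | None = None) -> AbdominalRecord:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, sig = data[:, 0], data[:, 1:].T
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    sid = subject_id or Path(path).stem
    return AbdominalRecord(signal=sig, fs=float(round(fs, 6)), subject_id=sid)


def write_annotations(peaks: np.ndarray, path: str | Path) -> None:
    """One peak sample index per line."""
    Path(path).write_text("".join(f"{int(p)}\n" for p in peaks))


def read_annotations(path: str | Path) -> np.ndarray:
    text = Path(path).read_text().split()
    return np.asarray([int(x) for x in text], dtype=np.int64)


def write_cohort(cohort: list[tuple[AbdominalRecord, GroundTruth]],
                 out_dir: str | Path) -> Path:
    """Write one CSV + annotation file per subject and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": []}
    for rec, gt in cohort:
        sid = rec.subject_id
        write_record(rec, out / f"{sid}.csv")
        write_annotations(gt.fetal_peak_samples, out / f"{sid}.fqrs.txt")
        write_annotations(gt.maternal_peak_samples, out / f"{sid}.mqrs.txt")
        manifest["subjects"].append({
            "id": sid, "fs": rec.fs, "n_samples": rec.n_samples,
            "record": f"{sid}.csv", "fetal_annotations": f"{sid}.fqrs.txt",
            "maternal_annotations": f"{sid}.mqrs.txt", "meta": rec.meta,
        })
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
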