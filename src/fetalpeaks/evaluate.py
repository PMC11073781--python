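"""Validation machinery.

Frame-level confusion metrics, ROC/AUC, Pearson correlation, Bland-Altman
agreement, k-fold and leave-one-subject-out cross-validation harnesses, and
stratified cohort summaries.  Frame-level accuracy (R-peak frame vs other)
is the primary metric; a beat-level tolerance match (detected peak within
+/-50 ms of a reference peak) is provided as a secondary metric for HR
validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm

__all__ = [
    "ConfusionSummary",
    "AgreementSummary",
    "confusion_metrics",
    "roc_auc",
    "pearson_r",
    "bland_altman",
    "kfold_cv",
    "loso_cv",
    "stratified_summary",
    "match_peaks",
    "round_half_even",
]


class EvaluationError(ValueError):
    pass


def round_half_even(x: float, decimals: int = 1) -> float:
    """Banker's rounding at a fixed decimal position, immune to binary
    representation noise near the half-way point."""
    guard = Decimal(1).scaleb(-(decimals + 6))
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x))).quantize(guard, rounding=ROUND_HALF_EVEN)
    return float(d.quantize(q, rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else 0.0

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else 0.0

    @property
    def f1_defined(self) -> bool:
        """False when there are no positives anywhere (F1 reported as 0)."""
        return (2 * self.tp + self.fp + self.fn) > 0

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "ppv": self.ppv, "npv": self.npv, "f1": self.f1}


def confusion_metrics(y_true, y_pred) -> ConfusionSummary:
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    if y_true.shape != y_pred.shape:
        raise EvaluationError(
            f"label shapes differ: {y_true.shape} vs {y_pred.shape}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# ROC / correlation / agreement
# ---------------------------------------------------------------------------

def roc_auc(y_true, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (fpr, tpr) and trapezoidal AUC over all thresholds."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise EvaluationError("AUC undefined: single-class truth")
    fpr, tpr, _ = skm.roc_curve(y_true, scores)
    return fpr, tpr, float(skm.auc(fpr, tpr))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise EvaluationError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EvaluationError("Pearson correlation undefined: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class AgreementSummary:
    bias: float        # mean of a - b
    loa_low: float     # bias - 1.96*SD(a - b)
    loa_high: float    # bias + 1.96*SD(a - b)
    sd: float
    n: int


def bland_altman(a, b) -> AgreementSummary:
    """Bias and 1.96-SD limits of agreement of paired differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise EvaluationError("paired series must have equal length")
    if a.size < 2:
        raise EvaluationError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementSummary(bias=bias, loa_low=bias - 1.96 * sd,
                            loa_high=bias + 1.96 * sd, sd=sd, n=a.size)


# ---------------------------------------------------------------------------
# Cross-validation harnesses
# ---------------------------------------------------------------------------

def _block_folds(n: int, k: int, seed: int, block: int = 50) -> list[np.ndarray]:
    """k disjoint folds over n frames built from contiguous blocks
    (shuffled with the seed), so neighbouring frames tend to share a fold."""
    if k < 2 or k > n:
        raise EvaluationError(f"cannot make {k} folds from {n} frames")
    block = max(1, min(block, n // k))   # at least one block per fold
    starts = np.arange(0, n, block)
    order = np.random.default_rng(seed).permutation(len(starts))
    folds: list[list[int]] = [[] for _ in range(k)]
    for j, bi in enumerate(order):
        s = starts[bi]
        folds[j % k].extend(range(s, min(s + block, n)))
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def kfold_cv(frames: np.ndarray, labels: np.ndarray, pipeline,
             k: int = 5, seed: int = 0) -> dict:
    """k-fold cross-validation over frames.

    ``pipeline(train_frames, train_labels, test_frames) -> predicted labels``.
    Returns per-fold ConfusionSummary plus the arithmetic mean of accuracy
    and F1 across folds.
    """
    labels = np.asarray(labels)
    n = len(labels)
    folds = _block_folds(n, k, seed)
    summaries = []
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        assert not np.any(train_mask[test_idx]), "fold leaked into training"
        pred = pipeline(frames[train_mask], labels[train_mask],
                        frames[test_idx])
        summaries.append(confusion_metrics(labels[test_idx], pred))
    return {
        "folds": summaries,
        "fold_indices": folds,
        "mean_accuracy": float(np.mean([s.accuracy for s in summaries])),
        "mean_f1": float(np.mean([s.f1 for s in summaries])),
    }


def loso_cv(cohort_framesets, pipeline, seed: int = 0) -> dict:
    """Leave-one-subject-out: train on all other subjects, test on the one.

    ``cohort_framesets`` is a list of FrameSet (one per subject);
    ``pipeline(train_frames, train_labels, test_frames) -> predicted labels``.
    Returns per-subject ConfusionSummary and the cohort mean +/- sample SD
    of accuracy.
    """
    if len(cohort_framesets) < 2:
        raise EvaluationError("leave-one-subject-out needs >= 2 subjects")
    per_subject = {}
    for i, held in enumerate(cohort_framesets):
        train_sets = [fs for j, fs in enumerate(cohort_framesets) if j != i]
        Xtr = np.concatenate([fs.frames for fs in train_sets])
        ytr = np.concatenate([fs.labels for fs in train_sets])
        pred = pipeline(Xtr, ytr, held.frames)
        per_subject[held.subject_id] = confusion_metrics(held.labels, pred)
    accs = np.asarray([s.accuracy for s in per_subject.values()])
    return {
        "per_subject": per_subject,
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# Stratified cohort summaries
# ---------------------------------------------------------------------------

def stratified_summary(table: pd.DataFrame, strata: dict,
                       value_col: str = "accuracy_pct",
                       decimals: int | None = None) -> dict:
    """Mean of `value_col` over the rows each stratum predicate selects.

    ``strata`` maps stratum name -> predicate(DataFrame) -> boolean mask.
    Empty strata are flagged and excluded.  When `decimals` is given, means
    are rounded half-even at that position.
    """
    out: dict[str, float] = {}
    for name, pred in strata.items():
        mask = np.asarray(pred(table), dtype=bool)
        if not mask.any():
            out[name] = float("nan")
            continue
        m = float(table.loc[mask, value_col].mean())
        out[name] = round_half_even(m, decimals) if decimals is not None else m
    return out


# ---------------------------------------------------------------------------
# Beat-level matching (secondary metric)
# ---------------------------------------------------------------------------

def match_peaks(detected: np.ndarray, reference: np.ndarray, fs: float,
                tol_ms: float = 50.0) -> dict:
    """Greedy one-to-one matching of detected to reference peaks within a
    +/-`tol_ms` window; reports sensitivity/PPV/F1 at the beat level."""
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    tol = tol_ms * fs / 1000.0
    used = np.zeros(len(reference), dtype=bool)
    tp = 0
    for d in detected:
        diffs = np.abs(reference - d)
        diffs[used] = np.inf
        if diffs.size and diffs.min() <= tol:
            used[int(np.argmin(diffs))] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(reference) - tp
    se = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "sensitivity": se, "ppv": ppv, "f1": f1}
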