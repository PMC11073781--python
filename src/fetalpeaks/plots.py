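"""Optional matplotlib figures for evaluation reports.

Requires the `plot` extra (matplotlib). Each function returns the figure
and optionally writes it to disk.
"""

from __future__ import annotations

import numpy as np

from .evaluate import AgreementSummary, ConfusionSummary


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def confusion_chart(cm: ConfusionSummary, path=None):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    counts = np.array([[cm.tn, cm.fp], [cm.fn, cm.tp]])
    ax.imshow(counts, cmap="Blues")
    for (i, j), v in np.ndenumerate(counts):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], ["Other", "R-peak"])
    ax.set_yticks([0, 1], ["Other", "R-peak"])
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    ax.set_title(f"Accuracy {cm.accuracy:.1%}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def roc_curve_plot(fpr, tpr, auc: float, path=None):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="gray", label="baseline")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def correlation_plot(x, y, r: float, path=None):
    plt = _mpl()
    x, y = np.asarray(x, float), np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12, alpha=0.7)
    coef = np.polyfit(x, y, 1)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, np.polyval(coef, grid), "r-", label=f"fit (r = {r:.2f})")
    ax.plot(grid, grid, ":", color="gold", label="identity")
    ax.set_xlabel("Reference HR (bpm)")
    ax.set_ylabel("Estimated HR (bpm)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def bland_altman_plot(a, b, summary: AgreementSummary, path=None):
    plt = _mpl()
    a, b = np.asarray(a, float), np.asarray(b, float)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    mean = (a + b) / 2
    diff = a - b
    ax.scatter(mean, diff, s=12, alpha=0.7)
    ax.axhline(summary.bias, ls="--", color="k", label="bias")
    for loa in (summary.loa_low, summary.loa_high):
        ax.axhline(loa, color="k", lw=1)
    ax.set_xlabel("Mean of methods (bpm)")
    ax.set_ylabel("Difference (bpm)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig
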