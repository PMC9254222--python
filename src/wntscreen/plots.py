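"""Summary figures for a fitted screen.

All plotting is best-effort and file-oriented: functions return the
matplotlib Axes and the pipeline writes deterministic file names.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

logger = logging.getLogger(__name__)

_HIT_COLORS = {"activator": "tab:red", "inhibitor": "tab:blue",
               "toxic": "tab:purple", "none": "0.7"}


def _scatter_by_class(ax, scores, x, y):
    for cls, color in _HIT_COLORS.items():
        sub = scores[scores["hit_class"] == cls]
        if not sub.empty:
            ax.scatter(sub[x], sub[y], s=12, c=color, label=cls, alpha=0.8)
    ax.legend(fontsize=7, loc="best")


def plot_volcano(results, ax=None):
    """Wnt log2FC vs −log10 p, with |log2FC| = 1 dashed guides."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    s = results.scores
    with np.errstate(divide="ignore"):
        s = s.assign(neglogp=-np.log10(s["min_p"]))
    _scatter_by_class(ax, s, "mean_log2fc_all_conc", "neglogp")
    for g in (-1.0, 1.0):
        ax.axvline(g, ls="--", c="k", lw=0.8)
    ax.axhline(-np.log10(results.thresholds.alpha), ls=":", c="k", lw=0.8)
    ax.set_xlabel("mean log2 fold change (Wnt ratio)")
    ax.set_ylabel("-log10 min p")
    return ax


def plot_health_vs_activity(results, ax=None):
    """Cell Health vs Wnt activation, toxicity guide at CH log2FC = −1."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    s = results.scores
    _scatter_by_class(ax, s, "mean_log2fc_all_conc", "mean_ch_log2fc_all_conc")
    ax.axhline(results.thresholds.toxicity_log2fc_cutoff, ls="--", c="k",
               lw=0.8)
    for g in (-1.0, 1.0):
        ax.axvline(g, ls="--", c="k", lw=0.8)
    ax.set_xlabel("mean log2 fold change (Wnt ratio)")
    ax.set_ylabel("mean Cell Health log2 fold change")
    return ax


def plot_exposure(prioritized, ax=None,
                  exposure_col="exposure_mgkgday_upper95"):
    """Predicted exposure vs Wnt Score, hits colored."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    _scatter_by_class(ax, prioritized, "wnt_score", exposure_col)
    ax.set_yscale("log")
    ax.set_xlabel("Wnt Score")
    ax.set_ylabel("predicted exposure (mg/kg-bw/day)")
    return ax


def plot_summary(results, out_dir, prioritized=None) -> list[Path]:
    """Write the standard figure set; returns the files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fn, arg in [
        ("volcano.png", plot_volcano, results),
        ("health_vs_activity.png", plot_health_vs_activity, results),
    ] + ([("exposure_vs_score.png", plot_exposure, prioritized)]
         if prioritized is not None else []):
        try:
            ax = fn(arg)
            path = out_dir / name
            ax.figure.savefig(path, dpi=120)
            plt.close(ax.figure)
            written.append(path)
        except Exception:  # plots are best-effort
            logger.exception("failed to render %s", name)
    return written
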