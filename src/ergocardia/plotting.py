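"""Figure helpers: log-log E_B curves and slope summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_eb_curves(curves, path: str | Path | None = None, ax=None):
    """Log-log E_B(t) curves: thin per-series lines plus a thick mean line.

    ``curves`` is an iterable of :class:`~ergocardia.ergodicity.EBCurve`
    sharing one duration grid.
    """
    curves = list(curves)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        ax.loglog(c.t_grid, np.maximum(c.eb_values, 1e-12), lw=0.7, alpha=0.5,
                  color="tab:gray")
    if curves:
        common = curves[0].t_grid
        mean_eb = np.mean([c.eb_values for c in curves], axis=0)
        ax.loglog(common, np.maximum(mean_eb, 1e-12), lw=2.5, color="tab:red",
                  label="mean")
        ax.legend(frameon=False)
    ax.set_xlabel("t")
    ax.set_ylabel(r"$E_B$")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_eb_slopes(eb_frame: pd.DataFrame, path: str | Path | None = None):
    """Per-target mean E_B decay slopes, original vs shuffled, across subjects."""
    summary = (
        eb_frame.groupby(["target", "variant"])["slope_loglog"].mean().unstack()
    )
    ax = summary.plot.bar(figsize=(6, 4), rot=30)
    ax.set_ylabel(r"mean log-log $E_B$ slope")
    ax.axhline(0, color="k", lw=0.5)
    ax.axhline(-1, color="k", lw=0.5, ls="--")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
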