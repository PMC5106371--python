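"""Reciprobit and per-cell frequency (violin) figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .recinormal import RecinormalParams, ReciprobitPoints, reciprobit_transform

_PROBIT_TICKS = [0.01, 0.05, 0.2, 0.5, 0.8, 0.95, 0.99]


def _axes(ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    return ax


def reciprobit_plot(points_by_label: dict, fits: dict | None = None, ax=None, out=None):
    """Reciprobit chart: reciprocal-time abscissa, probit ordinate.

    ``points_by_label`` maps condition labels to either interval arrays or
    :class:`ReciprobitPoints`; ``fits`` optionally maps the same labels to
    :class:`RecinormalParams` drawn as dashed ML lines.  The top axis shows
    interval duration (s); the right axis cumulative probability.
    """
    from scipy import stats

    ax = _axes(ax)
    for label, pts in points_by_label.items():
        if not isinstance(pts, ReciprobitPoints):
            pts = reciprobit_transform(pts)
        ax.plot(pts.abscissa, pts.ordinate, "o", ms=3, label=str(label))
    if fits:
        for label, params in fits.items():
            xs = np.linspace(-(params.mu_p + 3 * params.sigma_p), -1e-3, 100)
            ax.plot(xs, (xs + params.mu_p) / params.sigma_p, "--", lw=1)
    ax.set_xlabel("time (reciprocal scale, -1/t in 1/s)")
    ax.set_ylabel("z score")
    sec = ax.secondary_yaxis(
        "right", functions=(stats.norm.cdf, stats.norm.ppf)
    )
    sec.set_ylabel("cumulative probability")
    ax.legend(frameon=False)
    if out is not None:
        ax.figure.savefig(out, bbox_inches="tight")
    return ax


def frequency_violin_plot(datasets, ax=None, out=None):
    """Violin plot of instantaneous frequency (1/interval) per cell, pre vs stim."""
    from .datasets import IntervalDataset

    if isinstance(datasets, IntervalDataset):
        datasets = [datasets]
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    frame["frequency"] = 1.0 / frame["interval_s"]
    frame["cell"] = frame["patient"].astype(str) + "/" + frame["effector"].astype(str)

    ax = _axes(ax)
    cells = sorted(frame["cell"].unique())
    width = 0.35
    for i, cell in enumerate(cells):
        for j, cond in enumerate(("pre", "stim")):
            vals = frame.loc[(frame["cell"] == cell) & (frame["condition"] == cond), "frequency"]
            if vals.empty:
                continue
            pos = i + (j - 0.5) * 2 * width * 0.6
            parts = ax.violinplot(vals, positions=[pos], widths=width, showmeans=True)
            color = "C0" if cond == "pre" else "C3"
            for body in parts["bodies"]:
                body.set_facecolor(color)
    ax.set_xticks(range(len(cells)), cells)
    ax.set_ylabel("instantaneous frequency (Hz)")
    ax.set_title("pre (blue) vs stimulation (red)")
    if out is not None:
        ax.figure.savefig(out, bbox_inches="tight")
    return ax
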