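"""Event-stream to interval conversion and frequency statistics.

``events_to_intervals`` turns a timestamped movement stream into labelled
inter-movement intervals using a half-open window convention: an event at
exactly stimulation onset belongs to the stimulation window.  An interval is
labelled ``stim`` iff both bounding events lie in ``[onset, offset]`` and
``pre`` iff both lie in ``[onset - pre_window, onset)``; straddling intervals
and events outside both windows are discarded, with counts recorded so that
``pre + stim + discarded`` always equals the number of successive pairs.

``frequency_stats`` computes the per-cell (patient x effector x condition)
instantaneous-frequency summaries and an omnibus fixed-effects OLS analysis
with stimulation, effector, patient and their interactions as categorical
predictors.  This is a fixed-effects approximation of a mixed model with
patient as a random factor: with a handful of patients the random-effect
variance is ill-estimated, so the package deliberately reports the OLS
F-tests and flags the approximation in the report header.  Post hoc
pre-vs-stim comparisons are pooled-variance t-tests per cell, Bonferroni
adjusted over the number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datasets import IntervalDataset
from .exceptions import InsufficientDataError
from .simulate import EventStream

__all__ = ["WindowPolicy", "FrequencyReport", "events_to_intervals", "frequency_stats"]

APPROXIMATION_NOTE = (
    "Omnibus tests are a fixed-effects OLS approximation: patient enters as a "
    "categorical fixed factor, not a random effect."
)


@dataclass(frozen=True)
class WindowPolicy:
    """Analysis-window configuration.

    pre_window is the length of the baseline window ending at stimulation
    onset; None defaults to the stimulation duration so the two conditions
    are comparable in exposure.
    """

    pre_window: float | None = None


def events_to_intervals(stream: EventStream, policy: WindowPolicy | None = None) -> IntervalDataset:
    """Extract condition-labelled inter-movement intervals from one block.

    Raises :class:`InsufficientDataError` naming the empty window when either
    condition ends up with no intervals.  The returned dataset carries an
    ``extraction_counts`` dict with n_pairs / n_pre / n_stim / n_discarded
    (conservation: n_pre + n_stim + n_discarded == n_pairs).
    """
    policy = policy or WindowPolicy()
    onset, offset = stream.stim_onset, stream.stim_offset
    pre_window = policy.pre_window if policy.pre_window is not None else offset - onset
    pre_start = onset - pre_window

    t = stream.event_times
    if t.size < 2:
        raise InsufficientDataError("stream has fewer than 2 events; no intervals exist")
    a, b = t[:-1], t[1:]
    in_pre = lambda x: (x >= pre_start) & (x < onset)  # noqa: E731
    in_stim = lambda x: (x >= onset) & (x <= offset)  # noqa: E731
    pre_mask = in_pre(a) & in_pre(b)
    stim_mask = in_stim(a) & in_stim(b)

    counts = {
        "n_pairs": int(t.size - 1),
        "n_pre": int(pre_mask.sum()),
        "n_stim": int(stim_mask.sum()),
        "n_discarded": int(t.size - 1 - pre_mask.sum() - stim_mask.sum()),
    }
    for name, mask in (("pre", pre_mask), ("stim", stim_mask)):
        if not mask.any():
            raise InsufficientDataError(f"no intervals fall in the '{name}' analysis window")

    intervals = np.concatenate([(b - a)[pre_mask], (b - a)[stim_mask]])
    condition = np.array(["pre"] * counts["n_pre"] + ["stim"] * counts["n_stim"], dtype=object)
    step = stream.quantization_step
    if step is not None:
        intervals = np.round(intervals / step) * step  # kill float roundoff off the grid
    return IntervalDataset(
        intervals=intervals,
        condition=condition,
        effector=stream.effector,
        patient=stream.patient,
        quantization_step=step,
        extraction_counts=counts,
    )


@dataclass
class FrequencyReport:
    """Per-cell frequency summaries with omnibus and post hoc tests."""

    cells: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    excluded: list
    note: str = APPROXIMATION_NOTE

    def to_dict(self) -> dict:
        return {
            "note": self.note,
            "cells": self.cells.to_dict(orient="records"),
            "anova": self.anova.reset_index(names="term").to_dict(orient="records"),
            "posthoc": self.posthoc.to_dict(orient="records"),
            "excluded": list(self.excluded),
        }

    def to_text(self) -> str:
        lines = [self.note, "", "Per-cell instantaneous frequency (Hz):",
                 self.cells.to_string(index=False), "", "Omnibus (OLS F-tests):",
                 self.anova.to_string(), "", "Post hoc pre vs stim (Bonferroni adjusted):",
                 self.posthoc.to_string(index=False)]
        if self.excluded:
            lines += ["", f"Excluded cells (n < minimum): {self.excluded}"]
        return "\n".join(lines)


def frequency_stats(datasets, min_n: int = 2, alpha: float = 0.05) -> FrequencyReport:
    """Frequency summaries and tests over a collection of interval datasets.

    Instantaneous frequency is 1/interval.  Cells with fewer than ``min_n``
    intervals are excluded with a recorded warning, never silently.
    """
    if isinstance(datasets, IntervalDataset):
        datasets = [datasets]
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    frame["frequency"] = 1.0 / frame["interval_s"]

    counts = frame.groupby(["patient", "effector", "condition"], sort=True).size()
    excluded = [tuple(map(str, k)) for k, v in counts.items() if v < min_n]
    if excluded:
        keep = ~frame.set_index(["patient", "effector", "condition"]).index.isin(
            [k for k in counts.index if counts[k] < min_n]
        )
        frame = frame[keep.to_numpy() if hasattr(keep, "to_numpy") else keep]

    cells = (
        frame.groupby(["patient", "effector", "condition"], sort=True)["frequency"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )

    # omnibus: fixed-effects OLS with all categorical interactions
    terms = ["C(condition)", "C(effector)", "C(patient)"]
    n_eff = frame["effector"].nunique()
    n_pat = frame["patient"].nunique()
    formula = "frequency ~ C(condition)"
    if n_eff > 1:
        formula += " * C(effector)"
    if n_pat > 1:
        formula += " * C(patient)"
    model = smf.ols(formula, data=frame).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    # post hoc: pooled-variance t per patient x effector cell, Bonferroni
    rows = []
    for (patient, effector), grp in frame.groupby(["patient", "effector"], sort=True):
        pre = grp.loc[grp["condition"] == "pre", "frequency"]
        stim = grp.loc[grp["condition"] == "stim", "frequency"]
        if len(pre) < min_n or len(stim) < min_n:
            excluded.append((str(patient), str(effector), "posthoc"))
            continue
        t, p = sps.ttest_ind(stim, pre, equal_var=True)
        rows.append(
            {
                "patient": patient,
                "effector": effector,
                "mean_pre_hz": pre.mean(),
                "mean_stim_hz": stim.mean(),
                "t": float(t),
                "p_raw": float(p),
            }
        )
    posthoc = pd.DataFrame(rows)
    if not posthoc.empty:
        m = len(posthoc)
        posthoc["p_adjusted"] = np.minimum(1.0, posthoc["p_raw"] * m)
        posthoc["significant"] = posthoc["p_adjusted"] < alpha
    return FrequencyReport(cells=cells, anova=anova, posthoc=posthoc, excluded=excluded)
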