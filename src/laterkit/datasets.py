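"""Labelled inter-movement interval datasets and their CSV representation.

The on-disk format is a UTF-8 CSV with a required header and columns
``interval_s, condition, effector, patient`` ('.' decimal).  One
:class:`IntervalDataset` holds the intervals of a single patient x effector
recording with a per-interval condition label (``pre`` or ``stim``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CSV_COLUMNS = ["interval_s", "condition", "effector", "patient"]
CONDITIONS = ("pre", "stim")


@dataclass
class IntervalDataset:
    """Inter-movement intervals with condition labels for one patient/effector.

    quantization_step, when set, asserts that every interval is an integer
    multiple of that step (within floating tolerance) — the signature of
    event times sampled on a video-frame grid.
    """

    intervals: np.ndarray
    condition: np.ndarray
    effector: str = "manual"
    patient: str = "P1"
    quantization_step: float | None = None
    extraction_counts: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.condition.shape != self.intervals.shape:
            raise ValueError("condition labels must align one-to-one with intervals")
        if np.any(~np.isfinite(self.intervals)) or np.any(self.intervals <= 0):
            raise ValueError("all intervals must be finite and strictly > 0")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if self.quantization_step is not None:
            step = float(self.quantization_step)
            if step <= 0:
                raise ValueError("quantization_step must be > 0")
            mult = self.intervals / step
            if not np.allclose(mult, np.round(mult), atol=1e-6):
                raise ValueError("intervals are not multiples of quantization_step")

    def __len__(self) -> int:
        return self.intervals.size

    def by_condition(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        return self.intervals[self.condition == condition]

    @property
    def pre(self) -> np.ndarray:
        return self.by_condition("pre")

    @property
    def stim(self) -> np.ndarray:
        return self.by_condition("stim")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval_s": self.intervals,
                "condition": self.condition,
                "effector": self.effector,
                "patient": self.patient,
            }
        )


def write_intervals_csv(datasets, path) -> None:
    """Write one or more IntervalDatasets to a single CSV table."""
    if isinstance(datasets, IntervalDataset):
        datasets = [datasets]
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    frame.to_csv(path, index=False, columns=CSV_COLUMNS)


def read_intervals_csv(path, quantization_step: float | None = None) -> list[IntervalDataset]:
    """Read an interval CSV, returning one dataset per (patient, effector) group."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse interval CSV {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"interval CSV {path} is missing required columns {missing}")
    out = []
    for (patient, effector), grp in frame.groupby(["patient", "effector"], sort=True):
        out.append(
            IntervalDataset(
                intervals=grp["interval_s"].to_numpy(dtype=float),
                condition=grp["condition"].to_numpy(dtype=object),
                effector=str(effector),
                patient=str(patient),
                quantization_step=quantization_step,
            )
        )
    return out
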