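"""Serializable analysis reports and small CSV exports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .joint import ModelComparison, ThresholdRatioEstimate
from .recinormal import ReciprobitPoints


def write_reciprobit_csv(points: ReciprobitPoints, path) -> None:
    """Export reciprobit coordinates as a two-column CSV for external plotting."""
    pd.DataFrame({"abscissa": points.abscissa, "ordinate": points.ordinate}).to_csv(
        path, index=False
    )


def comparison_report(
    comparison: ModelComparison, ratio: ThresholdRatioEstimate | None = None
) -> dict:
    """JSON-ready model-comparison report: per-model fit stats, ranking,
    BIC-difference table with evidence labels, and the threshold ratio."""
    report = comparison.to_dict()
    if ratio is not None:
        report["threshold_ratio"] = ratio.to_dict()
    return report


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
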