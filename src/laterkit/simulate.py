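"""LATER race simulator and synthetic stimulation-experiment event streams.

The generator reproduces the statistical structure the analysis assumes: a
self-paced stream of movements whose inter-movement intervals are recinormal
(linear rise at a trial-varying Gaussian rate to a threshold), with an abrupt
condition switch at stimulation onset implemented as a reduction of the
baseline-to-threshold distance.  Scaling the threshold by a factor ``f``
scales both promptness parameters by ``1/f`` — a pure swivel: the reciprobit
intercept at infinite time is preserved exactly.  A shift mode (mean rate of
rise changed, promptness SD preserved) is provided for model-selection
calibration.  Options cover a minor early-response mixture component,
effector specificity, and 40 ms video-frame quantization of event times.

Defaults follow the study conditions the package targets: baseline movement
frequency 2.96 Hz and threshold factors 0.65 (manual) / 0.56 (vocal).  The
promptness coefficient of variation is not reported for that experiment; the
default 0.15 is a generator choice recorded in every manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import IntervalDataset
from .exceptions import InsufficientDataError
from .recinormal import RaceParams, RecinormalParams

__all__ = [
    "ExperimentConfig",
    "EventStream",
    "simulate_later",
    "simulate_experiment",
    "make_fixture_suite",
    "write_event_stream",
    "read_event_stream",
]


def _as_recinormal(params) -> tuple[RecinormalParams, float]:
    """Normalize either parameterization to (promptness params, theta)."""
    if isinstance(params, RaceParams):
        return params.to_recinormal(), params.theta
    if isinstance(params, RecinormalParams):
        return params, 1.0
    raise TypeError(f"params must be RaceParams or RecinormalParams, got {type(params)}")


def simulate_later(params, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` intervals from a LATER race.

    Per trial the rate of rise is drawn from ``N(mu_r, sigma_r)`` and redrawn
    while non-positive (a non-positive rate never reaches threshold); the
    interval is ``theta / rate``.  Equivalently, promptness is drawn from the
    zero-truncated promptness normal.  Deterministic given ``seed``; an
    existing :class:`numpy.random.Generator` may be passed instead.
    """
    rn, _theta = _as_recinormal(params)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.normal(rn.mu_p, rn.sigma_p, size=n)
    bad = p <= 0
    while bad.any():
        p[bad] = rng.normal(rn.mu_p, rn.sigma_p, size=int(bad.sum()))
        bad = p <= 0
    return 1.0 / p


@dataclass
class ExperimentConfig:
    """Parameters of one synthetic stimulation block.

    baseline_frequency is the mean promptness before stimulation (Hz);
    promptness_cv its coefficient of variation; threshold_factor the
    threshold ratio theta_stim/theta_pre applied inside the stimulation
    window (values < 1 accelerate behaviour).  ``stim_mode`` selects how the
    switch is realized: ``"swivel"`` scales both promptness parameters by
    1/threshold_factor (intercept preserved); ``"shift"`` scales only the
    mean (slope preserved).  When ``effector_specific`` is set and
    ``effector`` differs from ``stimulated_effector`` the stimulation window
    re-uses baseline parameters.
    """

    baseline_frequency: float = 2.96
    promptness_cv: float = 0.15
    threshold_factor: float = 0.65
    pre_duration: float = 60.0
    stim_duration: float = 60.0
    effector: str = "manual"
    stimulated_effector: str = "manual"
    effector_specific: bool = False
    stim_mode: str = "swivel"
    early_weight: float = 0.0
    early_params: RecinormalParams | None = None
    quantization_step: float | None = None
    patient: str = "SIM"
    block: str = "block1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_frequency <= 0:
            raise ValueError("baseline_frequency must be > 0")
        if not (0 < self.threshold_factor <= 1.5):
            raise ValueError("threshold_factor must lie in (0, 1.5]")
        if self.pre_duration <= 0 or self.stim_duration <= 0:
            raise ValueError("durations must be > 0")
        if not (0 < self.promptness_cv < 1):
            raise ValueError("promptness_cv must lie in (0, 1)")
        if self.stim_mode not in ("swivel", "shift"):
            raise ValueError("stim_mode must be 'swivel' or 'shift'")
        if not (0 <= self.early_weight < 0.5):
            raise ValueError("early_weight must lie in [0, 0.5)")
        if self.early_weight > 0 and self.early_params is None:
            raise ValueError("early_params required when early_weight > 0")
        if self.quantization_step is not None and self.quantization_step <= 0:
            raise ValueError("quantization_step must be > 0")

    @property
    def baseline_params(self) -> RecinormalParams:
        mu = self.baseline_frequency
        return RecinormalParams(mu, self.promptness_cv * mu)

    @property
    def stim_params(self) -> RecinormalParams:
        if self.effector_specific and self.effector != self.stimulated_effector:
            return self.baseline_params
        base = self.baseline_params
        if self.stim_mode == "swivel":
            return RecinormalParams(base.mu_p / self.threshold_factor, base.sigma_p / self.threshold_factor)
        return RecinormalParams(base.mu_p / self.threshold_factor, base.sigma_p)

    def to_manifest(self) -> dict:
        d = asdict(self)
        if self.early_params is not None:
            d["early_params"] = {"mu_p": self.early_params.mu_p, "sigma_p": self.early_params.sigma_p}
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if d.get("early_params") is not None:
            d["early_params"] = RecinormalParams(**d["early_params"])
        return cls(**d)


@dataclass
class EventStream:
    """Timestamped movement events with the block's stimulation window."""

    event_times: np.ndarray
    stim_onset: float
    stim_offset: float
    block: str = "block1"
    effector: str = "manual"
    patient: str = "SIM"
    quantization_step: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if not self.stim_onset < self.stim_offset:
            raise ValueError("stim_onset must precede stim_offset")
        if self.quantization_step is not None:
            mult = self.event_times / self.quantization_step
            if not np.allclose(mult, np.round(mult), atol=1e-6):
                raise ValueError("event times are not on the quantization grid")

    def __len__(self) -> int:
        return self.event_times.size


def _draw_interval(rng, cfg: ExperimentConfig, params: RecinormalParams) -> float:
    if cfg.early_weight > 0 and rng.random() < cfg.early_weight:
        params = cfg.early_params
    return float(simulate_later(params, 1, rng)[0])


def simulate_experiment(config: ExperimentConfig) -> EventStream:
    """Generate one stimulation-block event stream.

    Events are generated sequentially, ``t_{k+1} = t_k + T_k``; the interval
    draw uses baseline parameters while the current event precedes
    stimulation onset and stimulation parameters once it lies inside the
    window, so one draw naturally spans the onset boundary (the downstream
    labelling rules discard it).  Quantization, when configured, rounds
    *event times* (not intervals) to the nearest grid point, so frame error
    accumulates as it would in real video annotation.
    """
    rng = np.random.default_rng(config.seed)
    onset = config.pre_duration
    offset = config.pre_duration + config.stim_duration
    times = [0.0]
    t = 0.0
    while True:
        params = config.baseline_params if t < onset else config.stim_params
        t += _draw_interval(rng, config, params)
        if t > offset:
            break
        times.append(t)
    times = np.asarray(times)
    if config.quantization_step is not None:
        step = config.quantization_step
        times = np.round(times / step) * step
        times = np.unique(times)  # collisions would break strict monotonicity
        onset = round(onset / step) * step
        offset = round(offset / step) * step
    return EventStream(
        event_times=times,
        stim_onset=onset,
        stim_offset=offset,
        block=config.block,
        effector=config.effector,
        patient=config.patient,
        quantization_step=config.quantization_step,
        meta={"config": config.to_manifest()},
    )


def write_event_stream(stream: EventStream, csv_path, sidecar_path=None) -> None:
    """Write events as CSV (time_s, block, effector, patient) + JSON sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "time_s": stream.event_times,
            "block": stream.block,
            "effector": stream.effector,
            "patient": stream.patient,
        }
    ).to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    payload = {
        "stim_onset": stream.stim_onset,
        "stim_offset": stream.stim_offset,
        "block": stream.block,
        "effector": stream.effector,
        "patient": stream.patient,
        "quantization_step": stream.quantization_step,
        "meta": stream.meta,
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_event_stream(csv_path, sidecar_path=None) -> EventStream:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    for col in ("time_s", "block", "effector", "patient"):
        if col not in frame.columns:
            raise ValueError(f"event CSV {csv_path} is missing column {col!r}")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    info = json.loads(sidecar.read_text())
    return EventStream(
        event_times=frame["time_s"].to_numpy(dtype=float),
        stim_onset=float(info["stim_onset"]),
        stim_offset=float(info["stim_offset"]),
        block=str(frame["block"].iloc[0]),
        effector=str(frame["effector"].iloc[0]),
        patient=str(frame["patient"].iloc[0]),
        quantization_step=info.get("quantization_step"),
        meta=info.get("meta", {}),
    )


def make_fixture_suite(seed: int = 0, out_dir=None) -> dict:
    """Build the canonical synthetic fixtures (and optionally write them).

    Returns a mapping of fixture name to :class:`EventStream`: a swivel-truth
    stream (threshold factor 0.65), a shift-truth stream, a null stream
    (factor 1), a stream with a minor early component, and a 40 ms-quantized
    swivel stream.  Each stream's ``meta`` records its full generating
    configuration and seed; the same seed reproduces the suite exactly.
    """
    base = dict(baseline_frequency=2.96, promptness_cv=0.15, patient="SIM")
    ss = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    configs = {
        "swivel": ExperimentConfig(**base, threshold_factor=0.65, stim_mode="swivel", block="swivel", seed=seeds[0]),
        "shift": ExperimentConfig(**base, threshold_factor=0.65, stim_mode="shift", block="shift", seed=seeds[1]),
        "null": ExperimentConfig(**base, threshold_factor=1.0, block="null", seed=seeds[2]),
        "early": ExperimentConfig(
            **base,
            threshold_factor=0.65,
            early_weight=0.12,
            early_params=RecinormalParams(2.96 * 2.0, 2.96 * 2.0 * 0.15),
            block="early",
            seed=seeds[3],
        ),
        "quantized": ExperimentConfig(
            **base, threshold_factor=0.65, quantization_step=0.04, block="quantized", seed=seeds[4]
        ),
    }
    streams = {name: simulate_experiment(cfg) for name, cfg in configs.items()}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": seed, "fixtures": {}}
        for name, stream in streams.items():
            write_event_stream(stream, out_dir / f"{name}.csv")
            manifest["fixtures"][name] = {
                "csv": f"{name}.csv",
                "sidecar": f"{name}.json",
                "config": configs[name].to_manifest(),
            }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return streams
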