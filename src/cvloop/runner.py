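"""Scenario orchestration and artifact I/O.

A :class:`RunConfiguration` resolves a profile name, heart rate, cycle
count and disease settings into a fully concrete simulation;
:func:`run_scenario` executes it deterministically and (optionally) writes
the time-series CSV, an indices JSON, a copy of the resolved configuration
and a log file into an output directory. :func:`compare_runs` tabulates
absolute and relative index differences between two runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circulation import ValveConfiguration, simulate
from .disease import MR_GRADE_DELTAS, MS_GRADE_RATIOS
from .ecg import activation_from_fiducials, cycles_from_annotations, synthesize_ecg
from .indices import CardiacIndices, compute_indices
from .ppg import attach_ppg, ppg_features
from .profiles import DEFAULT_PROFILE, get_profile

__all__ = ["RunConfiguration", "ScenarioResult", "run_scenario", "compare_runs"]

logger = logging.getLogger("cvloop")


@dataclass(frozen=True)
class RunConfiguration:
    """A fully serialisable description of one simulation scenario."""

    profile: str = DEFAULT_PROFILE
    heart_rate_bpm: float = 75.0
    n_cycles: int = 12
    ms_grade: str | None = None
    mitral_resistance_ratio: float | None = None
    mr_grade: str | None = None
    delta_mi: float | None = None
    delta_ao: float = 0.0
    delta_tr: float = 0.0
    delta_pu: float = 0.0
    dt: float = 1e-4
    output_stride: int = 10
    seed: int = 0
    ecg_noise_std: float = 0.0
    output_dir: str | None = None
    parameter_overrides: dict = field(default_factory=dict)

    def resolve_mitral(self) -> tuple[float, float]:
        """(resistance ratio, delta_mi) from grades/explicit settings."""
        if self.ms_grade is not None and self.mitral_resistance_ratio is not None:
            raise ValueError("give either ms_grade or mitral_resistance_ratio, not both")
        if self.mr_grade is not None and self.delta_mi is not None:
            raise ValueError("give either mr_grade or delta_mi, not both")
        ratio = 1.0
        if self.ms_grade is not None:
            if self.ms_grade not in MS_GRADE_RATIOS:
                raise ValueError(f"unknown MS grade {self.ms_grade!r}")
            ratio = MS_GRADE_RATIOS[self.ms_grade]
        elif self.mitral_resistance_ratio is not None:
            ratio = float(self.mitral_resistance_ratio)
        delta = 0.0
        if self.mr_grade is not None:
            if self.mr_grade not in MR_GRADE_DELTAS:
                raise ValueError(f"unknown MR grade {self.mr_grade!r}")
            delta = MR_GRADE_DELTAS[self.mr_grade]
        elif self.delta_mi is not None:
            delta = float(self.delta_mi)
        return ratio, delta

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfiguration":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfiguration":
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        return cls.from_dict(data)


@dataclass
class ScenarioResult:
    """Bundle returned by :func:`run_scenario`."""

    config: RunConfiguration
    result: object  # SimulationResult
    indices: CardiacIndices
    ppg_features: list
    output_dir: Path | None = None


def _apply_overrides(obj, overrides: dict):
    if not overrides:
        return obj
    known = {f.name for f in dataclasses.fields(obj)}
    here = {k: v for k, v in overrides.items() if k in known}
    return dataclasses.replace(obj, **here) if here else obj


def run_scenario(config: RunConfiguration, write: bool | None = None) -> ScenarioResult:
    """Run one scenario end to end: ECG template -> timing -> closed-loop
    simulation -> indices and PPG features; optionally write artifacts.

    The run is deterministic given the configuration (the seed feeds the
    ECG generator's optional additive noise, which is off by default).
    """
    circ, comp, geometry, ppg_params = get_profile(config.profile)
    circ = _apply_overrides(circ, config.parameter_overrides)
    comp = _apply_overrides(comp, config.parameter_overrides)
    ratio, delta = config.resolve_mitral()
    if ratio != 1.0:
        circ = circ.with_mitral_resistance(ratio)
    valves = ValveConfiguration(
        delta_mi=delta, delta_ao=config.delta_ao, delta_tr=config.delta_tr, delta_pu=config.delta_pu
    )

    ecg = synthesize_ecg(
        config.heart_rate_bpm,
        n_cycles=config.n_cycles + 1,  # first R-R-partial cycle is discarded
        noise_std=config.ecg_noise_std,
        rng=config.seed,
    )
    cycles = cycles_from_annotations(ecg)
    timing = [activation_from_fiducials(f) for f in cycles[: config.n_cycles]]
    logger.info(
        "scenario profile=%s hr=%.1f cycles=%d ratio=%.3g delta_mi=%.3g",
        config.profile, config.heart_rate_bpm, config.n_cycles, ratio, delta,
    )
    result = simulate(
        circ, valves, comp, timing, n_cycles=config.n_cycles,
        dt=config.dt, output_stride=config.output_stride,
    )
    attach_ppg(result, ppg_params)
    indices = compute_indices(result, geometry=geometry, require_converged=False)
    first_steady = min(result.steady_state_cycle_index, result.n_cycles - 2)
    feats = ppg_features(result, cycles=[first_steady])

    out_dir = None
    if write or (write is None and config.output_dir):
        out_dir = Path(config.output_dir or "run")
        out_dir.mkdir(parents=True, exist_ok=True)
        write_timeseries_csv(result, out_dir / "timeseries.csv")
        (out_dir / "indices.json").write_text(
            json.dumps(indices.as_dict(), indent=2, sort_keys=True) + "\n"
        )
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        (out_dir / "run.log").write_text(
            f"profile={config.profile} hr={config.heart_rate_bpm} cycles={config.n_cycles} "
            f"ratio={ratio} delta_mi={delta} converged={result.converged} "
            f"steady_cycle={result.steady_state_cycle_index}\n"
        )
    return ScenarioResult(
        config=config, result=result, indices=indices, ppg_features=feats, output_dir=out_dir
    )


def write_timeseries_csv(result, path) -> None:
    """Dense traces as CSV: time, six pressures, four volumes, valve states,
    flows and the PPG column."""
    cols = {"time_s": result.time}
    for k, v in result.pressures.items():
        cols[f"P_{k}_mmHg"] = v
    for k, v in result.volumes.items():
        cols[f"V_{k}_mL"] = v
    for k, v in result.valve_states.items():
        cols[f"U_{k}"] = v
    for k, v in result.flows.items():
        cols[f"Q_{k}_mL_per_s"] = v
    if result.ppg is not None:
        cols["ppg"] = result.ppg
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def compare_runs(a: CardiacIndices, b: CardiacIndices) -> pd.DataFrame:
    """Tabular diff of two index sets: value_a, value_b, absolute and
    relative difference (b - a, relative to a)."""
    da, db = a.as_dict(), b.as_dict()
    if set(da) != set(db):
        raise ValueError("index schemas differ")
    rows = []
    for k in da:
        diff = db[k] - da[k]
        rel = diff / da[k] if da[k] != 0 else np.nan
        rows.append({"index": k, "a": da[k], "b": db[k], "abs_diff": diff, "rel_diff": rel})
    return pd.DataFrame(rows).set_index("index")
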