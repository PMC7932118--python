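"""Shared fixtures: one simulation per scenario, reused across test modules."""

from __future__ import annotations

import pytest

from cvloop.runner import RunConfiguration, run_scenario

MS_RATIOS = (5.0, 15.0, 50.0)
MR_DELTAS = (0.004, 0.024, 0.05)


@pytest.fixture(scope="session")
def healthy():
    """Healthy calibrated run at 75 bpm."""
    return run_scenario(RunConfiguration())


@pytest.fixture(scope="session")
def ms_runs():
    """Mitral stenosis runs keyed by resistance ratio (mild/severe/very severe)."""
    return {r: run_scenario(RunConfiguration(mitral_resistance_ratio=r)) for r in MS_RATIOS}


@pytest.fixture(scope="session")
def mr_runs():
    """Mitral regurgitation runs keyed by leak coefficient (mild/moderate/severe)."""
    return {d: run_scenario(RunConfiguration(delta_mi=d)) for d in MR_DELTAS}


def steady_cycle(scenario) -> int:
    """Index of the first steady cycle usable for per-cycle analysis."""
    res = scenario.result
    return min(res.steady_state_cycle_index, res.n_cycles - 2)
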