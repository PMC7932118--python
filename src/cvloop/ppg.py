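"""Peripheral photoplethysmogram (PPG) synthesis from the closed loop.

The peripheral blood-volume pulse is modelled as a weighted difference of
the systemic-artery pressure (forward flow into the capillary bed) and the
right-atrial pressure (venous return), scaled by the systemic resistance:

    p(t) = (k1 P_sa(t) - k2 P_ra(t)) / R_s

The trace is unit-free; only its morphology (systolic peak, dicrotic notch,
diastolic peak) and relative amplitudes are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circulation import SimulationResult

__all__ = ["PPGParameters", "synthesize_ppg", "attach_ppg", "ppg_features", "PPGCycleFeatures"]


@dataclass(frozen=True)
class PPGParameters:
    """Forward (k1) and reverse (k2) flow coefficients, dimensionless."""

    k1: float = 1.0
    k2: float = 2.5

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")


def synthesize_ppg(p_sa, p_ra, params: PPGParameters, R_s: float) -> np.ndarray:
    """Pointwise PPG trace from systemic-artery and right-atrial pressures."""
    p_sa = np.asarray(p_sa, dtype=float)
    p_ra = np.asarray(p_ra, dtype=float)
    if p_sa.shape != p_ra.shape:
        raise ValueError(f"trace shapes differ: {p_sa.shape} vs {p_ra.shape}")
    if R_s <= 0:
        raise ValueError("R_s must be > 0")
    return (params.k1 * p_sa - params.k2 * p_ra) / R_s


def attach_ppg(result: SimulationResult, params: PPGParameters | None = None) -> np.ndarray:
    """Compute the PPG trace for a simulation and store it on the result."""
    params = params or PPGParameters()
    trace = synthesize_ppg(
        result.pressures["sa"], result.pressures["ra"], params, result.params.R_s
    )
    result.ppg = trace
    return trace


@dataclass(frozen=True)
class PPGCycleFeatures:
    """Morphology of one PPG cycle.

    Amplitudes are measured from the cycle minimum; ``relative`` values are
    normalised by the systolic amplitude (scale-invariant). Diastolic/notch
    entries are None when the falling edge carries no secondary extremum.
    """

    systolic_peak: float
    systolic_amplitude: float
    systolic_time: float
    diastolic_amplitude: float | None
    diastolic_relative: float | None
    notch_time: float | None
    cycle_start: float
    cycle_length: float


def _cycle_features(t: np.ndarray, x: np.ndarray) -> PPGCycleFeatures:
    if np.ptp(x) <= 0:
        raise ValueError("flat PPG trace: no features to extract")
    i_sys = int(np.argmax(x))
    base = float(np.min(x))
    sys_amp = float(x[i_sys] - base)

    # secondary extremum pair (notch minimum then diastolic maximum) on the
    # falling edge after the systolic peak
    notch_time = dia_amp = dia_rel = None
    seg = x[i_sys:]
    if seg.size >= 3:
        interior = np.arange(1, seg.size - 1)
        mins = interior[(seg[interior] < seg[interior - 1]) & (seg[interior] <= seg[interior + 1])]
        if mins.size:
            i_notch = i_sys + int(mins[0])
            after = x[i_notch:]
            if after.size >= 3:
                interior2 = np.arange(1, after.size - 1)
                maxs = interior2[
                    (after[interior2] > after[interior2 - 1])
                    & (after[interior2] >= after[interior2 + 1])
                ]
                if maxs.size:
                    i_dia = i_notch + int(maxs[0])
                    notch_time = float(t[i_notch] - t[0])
                    dia_amp = float(x[i_dia] - base)
                    dia_rel = dia_amp / sys_amp if sys_amp > 0 else None
    return PPGCycleFeatures(
        systolic_peak=float(x[i_sys]),
        systolic_amplitude=sys_amp,
        systolic_time=float(t[i_sys] - t[0]),
        diastolic_amplitude=dia_amp,
        diastolic_relative=dia_rel,
        notch_time=notch_time,
        cycle_start=float(t[0]),
        cycle_length=float(t[-1] - t[0]),
    )


def ppg_features(result: SimulationResult, cycles=None) -> list[PPGCycleFeatures]:
    """Per-cycle PPG morphology features.

    ``cycles`` is an iterable of cycle indices; by default all cycles from
    the detected steady-state cycle onwards (except the last, see below) are
    analysed. The PPG trace is attached on demand. Because simulation cycles
    begin mid-diastole, each analysis window is re-anchored at the systolic
    peak and spans one full period into the following cycle, so the falling
    edge is contiguous; the last simulated cycle therefore cannot be
    analysed on its own.
    """
    if result.ppg is None:
        attach_ppg(result)
    if cycles is None:
        first = result.steady_state_cycle_index or 0
        cycles = range(min(first, result.n_cycles - 2), result.n_cycles - 1)
    feats = []
    for k in cycles:
        if k + 1 >= result.n_cycles:
            raise ValueError("PPG feature extraction needs the cycle after the requested one")
        sl = result.cycle_slice(k)
        n = sl.stop - sl.start
        ext = slice(sl.start, min(sl.stop + n, result.time.size))
        t, x = result.time[ext], result.ppg[ext]
        i_sys = int(np.argmax(x[:n]))
        feats.append(_cycle_features(t[i_sys : i_sys + n], x[i_sys : i_sys + n]))
    return feats
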