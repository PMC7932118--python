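"""Pressure-volume loop extraction and hemodynamic indices.

From one steady cycle of the closed-loop simulation this module derives the
standard echo/catheter indices: end-diastolic and end-systolic volume (EDV,
ESV) at the phase boundaries of the lv loop, stroke volume SV = EDV - ESV,
forward stroke volume (aortic forward volume, which is smaller than SV under
regurgitation), cardiac output CO = forward SV x HR, ejection fraction
EF = SV/EDV, mean arterial pressure as the time average of the systemic
arterial pressure, ESPVR/EDPVR as pressure-to-volume ratios at the loop
corners, and chamber diameters from an ellipsoidal volume model
d = sqrt(6 V / (pi k l)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .circulation import SimulationResult, segment_phases
from .disease import mitral_volumes

__all__ = [
    "ChamberGeometry",
    "PVLoop",
    "CardiacIndices",
    "NotSteadyError",
    "chamber_diameter",
    "extract_pv_loop",
    "compute_indices",
]


class NotSteadyError(RuntimeError):
    """Raised when indices are requested for a non-converged simulation."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Ellipsoid scale factors (dimensionless) and chamber lengths (cm)."""

    k_la: float = 1.2
    k_lv: float = 1.15
    l_la: float = 5.5
    l_lv: float = 8.0

    def __post_init__(self):
        if min(self.k_la, self.k_lv, self.l_la, self.l_lv) <= 0:
            raise ValueError("geometry constants must be positive")


@dataclass(frozen=True)
class PVLoop:
    """Ordered (volume mL, pressure mmHg) trace of one chamber over a cycle."""

    volume: np.ndarray
    pressure: np.ndarray
    chamber: str
    cycle: int

    def __post_init__(self):
        if self.volume.shape != self.pressure.shape or self.volume.ndim != 1:
            raise ValueError("volume and pressure must be 1-D arrays of equal length")

    def closure_gap(self) -> float:
        """Euclidean distance between first and last loop point, normalised
        by the loop's volume and pressure ranges."""
        dv = (self.volume[-1] - self.volume[0]) / max(np.ptp(self.volume), 1e-9)
        dp = (self.pressure[-1] - self.pressure[0]) / max(np.ptp(self.pressure), 1e-9)
        return math.hypot(dv, dp)


@dataclass(frozen=True)
class CardiacIndices:
    """Per-cycle hemodynamic indices (units in field names' docstring).

    Volumes mL, HR bpm, CO L/min, EF %, MAP mmHg, ESPVR/EDPVR mmHg/mL,
    diameters cm.
    """

    EDV: float
    ESV: float
    SV: float
    forward_SV: float
    HR: float
    CO: float
    EF: float
    MAP: float
    ESPVR: float
    EDPVR: float
    LVEDD: float
    LVESD: float
    LAEDD: float

    def __post_init__(self):
        if not self.ESV < self.EDV:
            raise ValueError("ESV must be smaller than EDV")
        if not 0.0 < self.EF < 100.0:
            raise ValueError(f"EF must lie in (0, 100), got {self.EF}")

    def as_dict(self) -> dict:
        return asdict(self)


def chamber_diameter(volume_ml: float, k: float, l_cm: float) -> float:
    """Ellipsoidal chamber diameter d = sqrt(6 V / (pi k l)).

    With k = 1 and l = d this reduces to the sphere relation V = pi d^3 / 6.
    """
    if volume_ml < 0:
        raise ValueError(f"volume must be >= 0, got {volume_ml}")
    if k <= 0 or l_cm <= 0:
        raise ValueError("k and l must be > 0")
    return math.sqrt(6.0 * volume_ml / (math.pi * k * l_cm))


def extract_pv_loop(result: SimulationResult, cycle: int, chamber: str = "lv") -> PVLoop:
    """One chamber's pressure-volume trajectory over cycle ``cycle``."""
    sl = result.cycle_slice(cycle)
    return PVLoop(
        volume=result.volumes[chamber][sl].copy(),
        pressure=result.pressures[chamber][sl].copy(),
        chamber=chamber,
        cycle=cycle,
    )


def compute_indices(
    result: SimulationResult,
    cycle: int | None = None,
    geometry: ChamberGeometry | None = None,
    require_converged: bool = True,
) -> CardiacIndices:
    """Hemodynamic indices from the steady cycle of a simulation.

    ``cycle`` defaults to the detected steady-state cycle; segmentation
    needs the following cycle in the record, so the last usable cycle is
    ``n_cycles - 2``. EDV/ESV are taken at the mitral-close and aortic-close
    phase boundaries; LAEDD is the la diameter at the lv end-diastolic
    instant.
    """
    geometry = geometry or ChamberGeometry()
    if cycle is None:
        if require_converged and not result.converged:
            raise NotSteadyError("simulation did not reach a steady limit cycle")
        cycle = min(result.steady_state_cycle_index, result.n_cycles - 2)
    phases = segment_phases(result, cycle)
    edv, esv = phases.edv, phases.esv
    T = result.timing[cycle].T
    hr = 60.0 / T

    sl = result.cycle_slice(cycle)
    t = result.time[sl]
    p_sa = result.pressures["sa"][sl]
    map_ = float(np.trapezoid(p_sa, t) / (t[-1] - t[0]))

    v_mi, v_ao, _ = mitral_volumes(result, cycle)
    sv = edv - esv
    forward_sv = v_ao
    co = forward_sv * hr / 1000.0
    ef = sv / edv * 100.0

    # pressure at the loop corners for the PV-ratio indices
    t_all = result.time
    p_lv = result.pressures["lv"]
    v_lv = result.volumes["lv"]
    i_ed = int(np.argmin(np.abs(t_all - phases.edv_time)))
    i_es = int(np.argmin(np.abs(t_all - phases.esv_time)))
    espvr = float(p_lv[i_es] / v_lv[i_es])
    edpvr = float(p_lv[i_ed] / v_lv[i_ed])

    v_la_at_ed = float(result.volumes["la"][i_ed])
    return CardiacIndices(
        EDV=edv,
        ESV=esv,
        SV=sv,
        forward_SV=forward_sv,
        HR=hr,
        CO=co,
        EF=ef,
        MAP=map_,
        ESPVR=espvr,
        EDPVR=edpvr,
        LVEDD=chamber_diameter(edv, geometry.k_lv, geometry.l_lv),
        LVESD=chamber_diameter(esv, geometry.k_lv, geometry.l_lv),
        LAEDD=chamber_diameter(v_la_at_ed, geometry.k_la, geometry.l_la),
    )
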