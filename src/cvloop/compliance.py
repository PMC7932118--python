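"""Time-varying chamber compliance functions and their derivatives.

Each heart chamber is a compliance vessel, V(t) = C(t) P(t) + V_s, whose
compliance is driven by a cosine activation phase-locked to the ECG. Atria
use a raised-cosine relaxation bump u(t) in [0, 2]; ventricles use a
piecewise half-cosine contraction u_v(t) in [0, 1] that rises to its
systolic peak at T1, relaxes until T2, and rests until the cycle ends.

Two ventricular conventions are supported:

* ``interpolated`` (default): C(t) = C_dia - (C_dia - C_sys) u_v(t-d),
  interpolating between a diastolic maximum and the end-systolic value.
  This keeps 1/C(t) bounded and lets the ventricle fill.
* ``literal``: C(t) = max(C_sys u_v(t-d), eps). Taken at face value the
  product form collapses to zero compliance in diastole, which makes the
  pressure equations singular; a small positive floor keeps them defined.
  Retained for fidelity experiments.

All functions accept scalars or numpy arrays for ``t`` and evaluate the
delayed activation argument periodically (mod T), so every compliance trace
is continuous and T-periodic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg import ActivationTiming

__all__ = [
    "ComplianceParameters",
    "atrial_activation",
    "atrial_activation_derivative",
    "ventricular_activation",
    "ventricular_activation_derivative",
    "atrial_compliance",
    "ventricular_compliance",
    "compliance",
    "compliance_derivative",
]

_ATRIA = ("ra", "la")
_VENTRICLES = ("lv", "rv")


def _wrap(t, T: float):
    """Periodic wrap of ``t`` into [0, T), robust to floating-point rounding."""
    x = np.mod(np.asarray(t, dtype=float), T)
    return np.where(x >= T, 0.0, x)


@dataclass(frozen=True)
class ComplianceParameters:
    """Chamber compliance extrema, all in mL/mmHg.

    ``C_lv``/``C_rv`` are the ventricular end-systolic values; in
    ``interpolated`` mode the diastolic maxima ``C_dia_lv``/``C_dia_rv``
    must also be given and exceed them.
    """

    C_min_ra: float
    C_max_ra: float
    C_min_la: float
    C_max_la: float
    C_lv: float
    C_rv: float
    ventricular_mode: str = "interpolated"
    C_dia_lv: float | None = None
    C_dia_rv: float | None = None
    epsilon_floor: float = 0.05

    def __post_init__(self):
        for name in ("C_min_ra", "C_max_ra", "C_min_la", "C_max_la", "C_lv", "C_rv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.C_max_ra < self.C_min_ra or self.C_max_la < self.C_min_la:
            raise ValueError("atrial C_max must be >= C_min")
        if self.ventricular_mode not in ("literal", "interpolated"):
            raise ValueError(f"unknown ventricular_mode {self.ventricular_mode!r}")
        if self.ventricular_mode == "interpolated":
            if self.C_dia_lv is None or self.C_dia_rv is None:
                raise ValueError("interpolated mode requires C_dia_lv and C_dia_rv")
            if self.C_dia_lv <= self.C_lv or self.C_dia_rv <= self.C_rv:
                raise ValueError("diastolic compliance must exceed the end-systolic value")
        if self.epsilon_floor <= 0:
            raise ValueError("epsilon_floor must be > 0")


def atrial_activation(t, T_a: float, T: float):
    """Atrial activation u(t): 0 before T_a, then 1 - cos(2pi (t-T_a)/(T-T_a)).

    Ranges over [0, 2]; ``t`` must lie within the cycle [0, T).
    """
    if not T_a < T:
        raise ValueError(f"need T_a < T, got T_a={T_a}, T={T}")
    tm = np.asarray(t, dtype=float)
    if np.any(tm < 0.0) or np.any(tm >= T):
        raise ValueError("t must lie within the cycle [0, T)")
    out = np.where(tm < T_a, 0.0, 1.0 - np.cos(2.0 * np.pi * (tm - T_a) / (T - T_a)))
    return out if out.ndim else float(out)


def atrial_activation_derivative(t, T_a: float, T: float):
    """d/dt of :func:`atrial_activation` (zero on the resting branch)."""
    if not T_a < T:
        raise ValueError(f"need T_a < T, got T_a={T_a}, T={T}")
    tm = np.asarray(t, dtype=float)
    if np.any(tm < 0.0) or np.any(tm >= T):
        raise ValueError("t must lie within the cycle [0, T)")
    w = 2.0 * np.pi / (T - T_a)
    out = np.where(tm < T_a, 0.0, w * np.sin(w * (tm - T_a)))
    return out if out.ndim else float(out)


def ventricular_activation(t, T1: float, T2: float, T: float):
    """Ventricular activation u_v(t): half-cosine rise on [0, T1), fall on
    [T1, T2), zero on [T2, T). Ranges over [0, 1]; ``t`` in [0, T)."""
    if not (0.0 < T1 < T2 <= T):
        raise ValueError(f"need 0 < T1 < T2 <= T, got T1={T1}, T2={T2}, T={T}")
    tm = np.asarray(t, dtype=float)
    if np.any(tm < 0.0) or np.any(tm >= T):
        raise ValueError("t must lie within the cycle [0, T)")
    rise = 0.5 - 0.5 * np.cos(np.pi * tm / T1)
    fall = 0.5 + 0.5 * np.cos(np.pi * (tm - T1) / (T2 - T1))
    out = np.where(tm < T1, rise, np.where(tm < T2, fall, 0.0))
    return out if out.ndim else float(out)


def ventricular_activation_derivative(t, T1: float, T2: float, T: float):
    """d/dt of :func:`ventricular_activation`."""
    if not (0.0 < T1 < T2 <= T):
        raise ValueError(f"need 0 < T1 < T2 <= T, got T1={T1}, T2={T2}, T={T}")
    tm = np.asarray(t, dtype=float)
    if np.any(tm < 0.0) or np.any(tm >= T):
        raise ValueError("t must lie within the cycle [0, T)")
    rise = 0.5 * np.pi / T1 * np.sin(np.pi * tm / T1)
    fall = -0.5 * np.pi / (T2 - T1) * np.sin(np.pi * (tm - T1) / (T2 - T1))
    out = np.where(tm < T1, rise, np.where(tm < T2, fall, 0.0))
    return out if out.ndim else float(out)


def atrial_compliance(t, chamber: str, params: ComplianceParameters, timing: ActivationTiming):
    """C(t) = C_min + 0.5 (C_max - C_min) u(.); la is delayed by d_la."""
    if chamber not in _ATRIA:
        raise ValueError(f"chamber must be one of {_ATRIA}, got {chamber!r}")
    delay = timing.d_la if chamber == "la" else 0.0
    c_min = params.C_min_la if chamber == "la" else params.C_min_ra
    c_max = params.C_max_la if chamber == "la" else params.C_max_ra
    u = atrial_activation(_wrap(np.asarray(t, dtype=float) - delay, timing.T), timing.T_a, timing.T)
    out = c_min + 0.5 * (c_max - c_min) * np.asarray(u)
    return out if out.ndim else float(out)


def ventricular_compliance(t, chamber: str, params: ComplianceParameters, timing: ActivationTiming):
    """Ventricular C(t) per the selected convention; activation argument t - d."""
    if chamber not in _VENTRICLES:
        raise ValueError(f"chamber must be one of {_VENTRICLES}, got {chamber!r}")
    c_sys = params.C_lv if chamber == "lv" else params.C_rv
    x = _wrap(np.asarray(t, dtype=float) - timing.d, timing.T)
    u = np.asarray(ventricular_activation(x, timing.T1, timing.T2, timing.T))
    if params.ventricular_mode == "literal":
        out = np.maximum(c_sys * u, params.epsilon_floor)
    else:
        c_dia = params.C_dia_lv if chamber == "lv" else params.C_dia_rv
        out = c_dia - (c_dia - c_sys) * u
    return out if out.ndim else float(out)


def compliance(t, chamber: str, params: ComplianceParameters, timing: ActivationTiming):
    """Dispatch to the atrial or ventricular compliance of ``chamber``."""
    if chamber in _ATRIA:
        return atrial_compliance(t, chamber, params, timing)
    return ventricular_compliance(t, chamber, params, timing)


def compliance_derivative(
    t, chamber: str, params: ComplianceParameters, timing: ActivationTiming
):
    """Analytic dC/dt for any chamber (zero on constant/floored branches)."""
    if chamber in _ATRIA:
        delay = timing.d_la if chamber == "la" else 0.0
        c_min = params.C_min_la if chamber == "la" else params.C_min_ra
        c_max = params.C_max_la if chamber == "la" else params.C_max_ra
        x = _wrap(np.asarray(t, dtype=float) - delay, timing.T)
        du = np.asarray(atrial_activation_derivative(x, timing.T_a, timing.T))
        out = 0.5 * (c_max - c_min) * du
        return out if out.ndim else float(out)
    if chamber not in _VENTRICLES:
        raise ValueError(f"unknown chamber {chamber!r}")
    c_sys = params.C_lv if chamber == "lv" else params.C_rv
    x = _wrap(np.asarray(t, dtype=float) - timing.d, timing.T)
    du = np.asarray(ventricular_activation_derivative(x, timing.T1, timing.T2, timing.T))
    if params.ventricular_mode == "literal":
        u = np.asarray(ventricular_activation(x, timing.T1, timing.T2, timing.T))
        above_floor = c_sys * u > params.epsilon_floor
        out = np.where(above_floor, c_sys * du, 0.0)
    else:
        c_dia = params.C_dia_lv if chamber == "lv" else params.C_dia_rv
        out = -(c_dia - c_sys) * du
    return out if out.ndim else float(out)
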