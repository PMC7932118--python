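"""Mitral valve disease parameterisation.

Mitral stenosis (MS) narrows the valve orifice and is modelled as a raised
trans-mitral resistance. Clinical grades map to resistance ratios over the
healthy value: mild 5x, severe 15x, very severe 50x. An orifice-area
formula relating the stenotic area A_MS to the diseased resistance is also
exposed in both orientations; note that the proportional ("as printed")
orientation makes resistance *fall* as the orifice narrows, which
contradicts both the grade table and the physics of an orifice, so grade
presets (ratios) are the default pathway and the inverted orientation is
the physically sensible one.

Mitral regurgitation (MR) is an incompetent valve: during systole the leak
coefficient delta_mi of the valve law lets blood flow backwards lv -> la.
Severity is quantified by the regurgitation fraction
RF = (V_mi - V_ao) / V_mi x 100, the percentage of trans-mitral volume that
never reaches the aorta. Grade presets: mild delta=0.004, moderate 0.024,
severe 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circulation import SimulationResult

__all__ = [
    "StenosisSpecification",
    "RegurgitationSpecification",
    "MS_GRADE_RATIOS",
    "MR_GRADE_DELTAS",
    "NORMAL_MITRAL_AREA_CM2",
    "stenotic_resistance",
    "mitral_volumes",
    "regurgitant_fraction",
    "classify_ms_area",
    "classify_mr_rf",
]

#: Resistance ratios (diseased / healthy trans-mitral resistance) per MS grade.
MS_GRADE_RATIOS = {"mild": 5.0, "severe": 15.0, "very_severe": 50.0}

#: Leak coefficient per MR grade.
MR_GRADE_DELTAS = {"mild": 0.004, "moderate": 0.024, "severe": 0.05}

#: Normal effective mitral orifice area.
NORMAL_MITRAL_AREA_CM2 = 4.0

#: Valve-area bands (cm^2) used for MS grading: mild > 1.5, severe 1.0-1.5,
#: very severe < 1.0.
_MS_AREA_BANDS = (("very_severe", 1.0), ("severe", 1.5))

#: RF bands (%) for MR grading: mild < 30, moderate 30-49, severe > 49.
_MR_RF_BANDS = (("mild", 30.0), ("moderate", 49.0))


def stenotic_resistance(
    A_MS: float,
    R_mi: float,
    A_N: float = NORMAL_MITRAL_AREA_CM2,
    formula: str = "inverted",
) -> float:
    """Diseased trans-mitral resistance from the stenotic orifice area.

    ``inverted`` (default): R_d = (A_N / A_MS) R_mi — resistance grows as the
    orifice narrows. ``as_printed``: R_d = (A_MS / A_N) R_mi.
    """
    if A_MS <= 0 or A_N <= 0:
        raise ValueError("orifice areas must be > 0")
    if A_MS > A_N:
        raise ValueError(f"stenotic area {A_MS} exceeds the normal area {A_N}")
    if formula == "as_printed":
        return (A_MS / A_N) * R_mi
    if formula == "inverted":
        return (A_N / A_MS) * R_mi
    raise ValueError(f"formula must be 'as_printed' or 'inverted', got {formula!r}")


@dataclass(frozen=True)
class StenosisSpecification:
    """A graded or area-specified mitral stenosis.

    Construct via :meth:`from_grade` (ratio presets, the default pathway) or
    :meth:`from_area` (orifice-area formula).
    """

    resistance_ratio: float
    grade: str | None = None
    A_MS: float | None = None

    def __post_init__(self):
        if self.resistance_ratio < 1.0:
            raise ValueError("diseased resistance cannot be below the healthy value")

    @classmethod
    def from_grade(cls, grade: str) -> "StenosisSpecification":
        if grade not in MS_GRADE_RATIOS:
            raise ValueError(f"grade must be one of {sorted(MS_GRADE_RATIOS)}, got {grade!r}")
        return cls(resistance_ratio=MS_GRADE_RATIOS[grade], grade=grade)

    @classmethod
    def from_area(
        cls, A_MS: float, A_N: float = NORMAL_MITRAL_AREA_CM2, formula: str = "inverted"
    ) -> "StenosisSpecification":
        ratio = stenotic_resistance(A_MS, 1.0, A_N, formula=formula)
        return cls(resistance_ratio=max(ratio, 1.0), grade=classify_ms_area(A_MS), A_MS=A_MS)

    def diseased_resistance(self, R_mi_healthy: float) -> float:
        return self.resistance_ratio * R_mi_healthy


@dataclass(frozen=True)
class RegurgitationSpecification:
    """A graded or coefficient-specified mitral regurgitation."""

    delta_mi: float
    grade: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.delta_mi < 1.0):
            raise ValueError(f"delta_mi must be in [0, 1), got {self.delta_mi}")

    @classmethod
    def from_grade(cls, grade: str) -> "RegurgitationSpecification":
        if grade not in MR_GRADE_DELTAS:
            raise ValueError(f"grade must be one of {sorted(MR_GRADE_DELTAS)}, got {grade!r}")
        return cls(delta_mi=MR_GRADE_DELTAS[grade], grade=grade)


def classify_ms_area(A_MS: float) -> str:
    """MS grade from the stenotic orifice area (cm^2)."""
    if A_MS <= 0:
        raise ValueError("area must be > 0")
    for grade, upper in _MS_AREA_BANDS:
        if A_MS < upper:
            return grade
    return "mild"


def classify_mr_rf(rf_percent: float) -> str:
    """MR grade from the regurgitation fraction (%)."""
    if not 0.0 <= rf_percent < 100.0:
        raise ValueError(f"RF must be in [0, 100), got {rf_percent}")
    for grade, upper in _MR_RF_BANDS:
        if rf_percent < upper:
            return grade
    return "severe"


def mitral_volumes(result: SimulationResult, cycle: int) -> tuple[float, float, float]:
    """(forward mitral, forward aortic, mitral backflow) volumes in mL over
    one cycle, by trapezoidal integration of the rectified flow traces."""
    sl = result.cycle_slice(cycle)
    t = result.time[sl]
    q_mi = result.flows["mi"][sl]
    q_ao = result.flows["ao"][sl]
    v_mi = float(np.trapezoid(np.maximum(q_mi, 0.0), t))
    v_back = float(np.trapezoid(np.maximum(-q_mi, 0.0), t))
    v_ao = float(np.trapezoid(np.maximum(q_ao, 0.0), t))
    return v_mi, v_ao, v_back


def regurgitant_fraction(v_mi: float, v_ao: float) -> float:
    """RF = (V_mi - V_ao)/V_mi x 100, the share of trans-mitral volume lost
    to backflow."""
    if v_mi <= 0:
        raise ZeroDivisionError("regurgitant fraction undefined for V_mi <= 0")
    return (v_mi - v_ao) / v_mi * 100.0
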