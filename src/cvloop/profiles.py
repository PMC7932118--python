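"""Shipped parameter profiles.

``published``
    The published constant table verbatim: valve and vascular resistances,
    arterial compliances, atrial compliance extrema, ventricular
    end-systolic compliances, unstressed volumes and initial pressures,
    with the ventricular ``literal`` compliance convention (floored).
    Shipped for fidelity experiments; as printed it cannot reproduce the
    published healthy indices (its systemic resistance of 0.05 mmHg·s/mL
    gives a systemic pressure drop of ~4 mmHg at 5 L/min, two orders of
    magnitude below a physiological MAP), and the zero-floored ventricular
    compliance forbids realistic filling.

``calibrated``
    The working default. Same model structure; resistances, compliances and
    initial pressures tuned (coordinate-descent on the healthy steady-state
    targets CO 5.2 L/min, EF 56 %, MAP 101 mmHg, LVEDV 125 mL / LVESV 55 mL,
    with the regurgitation-fraction and stenosis severity responses as joint
    constraints) and the ``interpolated`` ventricular convention with
    explicit diastolic compliances. See docs/methods.md for the calibration
    account. Disease severities are applied to this profile as ratios
    (stenosis) or leak coefficients (regurgitation), so grade presets stay
    meaningful.
"""

from __future__ import annotations

from .compliance import ComplianceParameters
from .circulation import CirculationParameters
from .indices import ChamberGeometry
from .ppg import PPGParameters

__all__ = ["get_profile", "PROFILES", "DEFAULT_PROFILE"]

DEFAULT_PROFILE = "calibrated"


def _published():
    circulation = CirculationParameters(
        R_mi=0.002,
        R_ao=0.002,
        R_tr=0.001,
        R_pu=0.001,
        R_s=0.05,
        R_p=0.01,
        C_sa=0.2,
        C_pa=5.0,
        V_s={"la": 5.0, "lv": 15.0, "ra": 5.0, "rv": 40.0},
        P0={"la": 5.0, "lv": 5.0, "sa": 80.0, "ra": 5.0, "rv": 5.0, "pa": 15.0},
        profile_name="published",
    )
    compliance = ComplianceParameters(
        C_min_ra=0.2,
        C_max_ra=0.3,
        C_min_la=0.2,
        C_max_la=0.3,
        C_lv=2.5,
        C_rv=1.0,
        ventricular_mode="literal",
        epsilon_floor=0.05,
    )
    return circulation, compliance


def _calibrated():
    circulation = CirculationParameters(
        R_mi=0.002,
        R_ao=0.01,
        R_tr=0.005,
        R_pu=0.005,
        R_s=1.08,
        R_p=0.08,
        C_sa=1.6,
        C_pa=4.0,
        V_s={"la": 5.0, "lv": 30.0, "ra": 5.0, "rv": 40.0},
        P0={"la": 8.5, "lv": 8.5, "sa": 100.0, "ra": 5.0, "rv": 5.0, "pa": 16.0},
        profile_name="calibrated",
    )
    compliance = ComplianceParameters(
        C_min_ra=3.0,
        C_max_ra=4.5,
        C_min_la=3.0,
        C_max_la=4.5,
        C_lv=0.20,
        C_rv=0.6,
        ventricular_mode="interpolated",
        C_dia_lv=10.0,
        C_dia_rv=14.0,
    )
    return circulation, compliance


PROFILES = {"published": _published, "calibrated": _calibrated}


def get_profile(name: str = DEFAULT_PROFILE):
    """(CirculationParameters, ComplianceParameters, ChamberGeometry,
    PPGParameters) for a named profile."""
    try:
        factory = PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown profile {name!r}; available: {sorted(PROFILES)}") from None
    circulation, compliance = factory()
    return circulation, compliance, ChamberGeometry(), PPGParameters()
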