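"""Romhilt-Estes-style ECG point scores for left-atrial enlargement and
left-ventricular hypertrophy.

Inputs are multi-lead ECG measurements (durations in ms, amplitudes in mm
at standard gain, 1 mm = 0.1 mV), not raw waveforms. The la-enlargement
score awards 5 points per satisfied P-wave criterion (lead II bifid-P peak
separation > 40 ms, lead II P duration > 110 ms, lead V1 terminal-negative
P duration > 40 ms, lead V1 terminal-negative P amplitude >= 1 mm); a total
of 15 or more flags enlargement. The lv-hypertrophy score sums voltage,
ST-T, atrial, QRS-duration and intrinsicoid-deflection items; 5 or more
flags hypertrophy. The ST-T item scores 3 without digitalis but only 1
with digitalis, the standard weighting.

Measured values recorded as threshold-qualifying ("at least 1 mm", "at
least 50 ms") are treated as satisfying their criteria, so the amplitude
and intrinsicoid comparisons use >= at those two thresholds.

A packaged fixture CSV ships the measurements of three mitral-valve-disease
patients (ids 107, 110, 188) from a public ECG database.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from importlib import resources

import pandas as pd

__all__ = [
    "ECGLeadFeatures",
    "ScoreResult",
    "la_enlargement_score",
    "lv_hypertrophy_score",
    "threshold_flag",
    "load_feature_table",
    "load_packaged_patients",
    "score_table",
    "LA_ABNORMAL_THRESHOLD",
    "LV_ABNORMAL_THRESHOLD",
]

LA_ABNORMAL_THRESHOLD = 15
LV_ABNORMAL_THRESHOLD = 5

_LA_FIELDS = (
    "leadII_p_peak_separation",
    "leadII_p_duration",
    "leadV1_p_terminal_neg_duration",
    "leadV1_p_terminal_neg_amplitude",
)
_LV_FIELDS = (
    "leadI_R_amp",
    "leadIII_S_amp",
    "leadV1_S_amp",
    "leadV2_S_amp",
    "leadV5_R_amp",
    "leadV6_R_amp",
    "stt_opposite_qrs_without_digitalis",
    "stt_opposite_qrs_with_digitalis",
    "left_atrial_enlargement_present",
    "qrs_duration",
    "leadV5_intrinsicoid",
    "leadV6_intrinsicoid",
)


class MissingFeatureError(ValueError):
    """A required measurement is absent (None/NaN)."""


@dataclass(frozen=True)
class ECGLeadFeatures:
    """Multi-lead ECG measurements: durations ms, amplitudes mm."""

    leadII_p_peak_separation: float
    leadII_p_duration: float
    leadV1_p_terminal_neg_duration: float
    leadV1_p_terminal_neg_amplitude: float
    leadI_R_amp: float
    leadIII_S_amp: float
    leadV1_S_amp: float
    leadV2_S_amp: float
    leadV5_R_amp: float
    leadV6_R_amp: float
    stt_opposite_qrs_without_digitalis: bool
    stt_opposite_qrs_with_digitalis: bool
    left_atrial_enlargement_present: bool
    qrs_duration: float
    leadV5_intrinsicoid: float
    leadV6_intrinsicoid: float

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.type == "bool" or isinstance(v, bool):
                continue
            if v is None or v != v:  # None or NaN
                raise MissingFeatureError(f"missing measurement: {f.name}")
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        if self.stt_opposite_qrs_without_digitalis and self.stt_opposite_qrs_with_digitalis:
            raise ValueError("the two digitalis ST-T flags cannot both be true")


@dataclass(frozen=True)
class ScoreResult:
    """A point score with its per-criterion breakdown (summing to the score)."""

    score: int
    breakdown: dict

    def __post_init__(self):
        if sum(self.breakdown.values()) != self.score:
            raise ValueError("breakdown does not sum to the score")


def la_enlargement_score(f: ECGLeadFeatures) -> ScoreResult:
    """Left-atrial enlargement: 5 points per satisfied P-wave criterion."""
    breakdown = {
        "leadII_peak_separation_gt_40ms": 5 if f.leadII_p_peak_separation > 40.0 else 0,
        "leadII_p_duration_gt_110ms": 5 if f.leadII_p_duration > 110.0 else 0,
        "leadV1_terminal_neg_duration_gt_40ms": 5 if f.leadV1_p_terminal_neg_duration > 40.0 else 0,
        "leadV1_terminal_neg_amplitude_ge_1mm": 5
        if f.leadV1_p_terminal_neg_amplitude >= 1.0
        else 0,
    }
    return ScoreResult(score=sum(breakdown.values()), breakdown=breakdown)


def lv_hypertrophy_score(f: ECGLeadFeatures) -> ScoreResult:
    """Left-ventricular hypertrophy point score.

    3 points if any voltage criterion holds (limb-lead R or S >= 20 mm,
    S in V1/V2 >= 30 mm, R in V5/V6 >= 30 mm); 3 for an ST-T vector opposite
    the QRS without digitalis (1 with digitalis); 3 for left-atrial
    enlargement; 1 for QRS duration >= 90 ms; 1 for a delayed intrinsicoid
    deflection >= 50 ms in V5 or V6.
    """
    voltage = (
        max(f.leadI_R_amp, f.leadIII_S_amp) >= 20.0
        or max(f.leadV1_S_amp, f.leadV2_S_amp) >= 30.0
        or max(f.leadV5_R_amp, f.leadV6_R_amp) >= 30.0
    )
    breakdown = {
        "voltage": 3 if voltage else 0,
        "stt_without_digitalis": 3 if f.stt_opposite_qrs_without_digitalis else 0,
        "stt_with_digitalis": 1 if f.stt_opposite_qrs_with_digitalis else 0,
        "left_atrial_enlargement": 3 if f.left_atrial_enlargement_present else 0,
        "qrs_duration_ge_90ms": 1 if f.qrs_duration >= 90.0 else 0,
        "intrinsicoid_ge_50ms": 1
        if max(f.leadV5_intrinsicoid, f.leadV6_intrinsicoid) >= 50.0
        else 0,
    }
    return ScoreResult(score=sum(breakdown.values()), breakdown=breakdown)


def threshold_flag(score: int, kind: str) -> str:
    """'normal' or 'abnormal': la abnormal at >= 15 points, lv at >= 5."""
    if score < 0:
        raise ValueError("score must be >= 0")
    if kind == "la":
        return "abnormal" if score >= LA_ABNORMAL_THRESHOLD else "normal"
    if kind == "lv":
        return "abnormal" if score >= LV_ABNORMAL_THRESHOLD else "normal"
    raise ValueError(f"kind must be 'la' or 'lv', got {kind!r}")


_BOOL_MAP = {"yes": True, "no": False, "true": True, "false": False, "1": True, "0": False}


def _coerce_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ValueError(f"cannot interpret {v!r} as a boolean")


def load_feature_table(path) -> dict[str, ECGLeadFeatures]:
    """Read a feature CSV (one row per subject, `patient_id` column plus the
    :class:`ECGLeadFeatures` field names) into a dict keyed by patient id."""
    df = pd.read_csv(path, dtype=str)
    if "patient_id" not in df.columns:
        raise ValueError("feature table needs a 'patient_id' column")
    out = {}
    bool_fields = {
        "stt_opposite_qrs_without_digitalis",
        "stt_opposite_qrs_with_digitalis",
        "left_atrial_enlargement_present",
    }
    for _, row in df.iterrows():
        kwargs = {}
        for f in dc_fields(ECGLeadFeatures):
            if f.name not in row or pd.isna(row[f.name]):
                raise MissingFeatureError(f"missing measurement: {f.name}")
            raw = row[f.name]
            kwargs[f.name] = _coerce_bool(raw) if f.name in bool_fields else float(raw)
        out[str(row["patient_id"])] = ECGLeadFeatures(**kwargs)
    return out


def load_packaged_patients() -> dict[str, ECGLeadFeatures]:
    """The packaged measurement fixture for patients 107, 110 and 188."""
    with resources.files("cvloop.data").joinpath("patients.csv").open("r") as fh:
        return load_feature_table(fh)


def score_table(features: dict[str, ECGLeadFeatures]) -> pd.DataFrame:
    """Both scores and their normal/abnormal flags for a set of subjects."""
    rows = []
    for pid, f in features.items():
        la = la_enlargement_score(f)
        lv = lv_hypertrophy_score(f)
        rows.append(
            {
                "patient_id": pid,
                "la_score": la.score,
                "la_flag": threshold_flag(la.score, "la"),
                "lv_score": lv.score,
                "lv_flag": threshold_flag(lv.score, "lv"),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
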