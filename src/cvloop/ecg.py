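"""Synthetic single-lead ECG generation, PQRST fiducial detection, and the
mapping from fiducial times to the activation-timing parameters that drive
the time-varying compliance functions.

The generator produces a clean sum-of-Gaussians PQRST template with known,
annotated fiducial instants; it stands in for a measured single-lead ECG.
Cycles are delimited R-to-R. Because the activation mapping needs the P, Q,
R, S and T instants of one beat expressed relative to a cycle origin that
precedes the P wave, each cycle is anchored at ``R - r_frac * RR`` with
``r_frac`` defaulting to the generator's R-phase fraction (0.26), which
places the cycle boundary inside the electrically quiet TP segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d

__all__ = [
    "ECGSignal",
    "CycleFiducials",
    "ActivationTiming",
    "ECGMorphology",
    "synthesize_ecg",
    "detect_fiducials",
    "activation_from_fiducials",
    "load_ecg_csv",
    "DEFAULT_R_FRACTION",
]

#: Default phase of the R peak within a cardiac cycle (fraction of the cycle
#: length); doubles as the detector's cycle-anchor offset.
DEFAULT_R_FRACTION = 0.26


class FiducialDetectionError(RuntimeError):
    """Raised when fewer than two R peaks (or no usable cycle) can be found."""


@dataclass(frozen=True)
class ECGMorphology:
    """Fractional PQRST positions, amplitudes (mV) and Gaussian widths.

    Positions are fractions of the cycle length and must be strictly
    increasing within (0, 1); widths are fractions of the cycle length.
    """

    positions: dict = field(
        default_factory=lambda: {"P": 0.12, "Q": 0.22, "R": 0.26, "S": 0.30, "T": 0.55}
    )
    amplitudes: dict = field(
        default_factory=lambda: {"P": 0.15, "Q": -0.10, "R": 1.00, "S": -0.20, "T": 0.30}
    )
    widths: dict = field(
        default_factory=lambda: {"P": 0.025, "Q": 0.008, "R": 0.010, "S": 0.009, "T": 0.050}
    )

    def validate(self) -> None:
        waves = ["P", "Q", "R", "S", "T"]
        pos = [self.positions[w] for w in waves]
        if not all(0.0 < a < b < 1.0 for a, b in zip(pos, pos[1:])) or not 0.0 < pos[0]:
            raise ValueError(
                "morphology positions must be strictly increasing fractions in (0, 1), "
                f"got {self.positions}"
            )
        if any(self.widths[w] <= 0 for w in waves):
            raise ValueError("morphology widths must be positive")
        if self.amplitudes["R"] <= 0:
            raise ValueError("R amplitude must be positive for peak detection")


@dataclass(frozen=True)
class ECGSignal:
    """A sampled single-lead ECG.

    samples are in mV (unit-free accepted); ``annotations`` carries the
    generator's ground-truth fiducial times in seconds (absolute), keyed by
    wave label, when the signal is synthetic.
    """

    samples: np.ndarray
    sampling_rate: float
    annotations: dict | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if samples.ndim != 1:
            raise ValueError("ECG samples must be a 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class CycleFiducials:
    """PQRST instants of one cardiac cycle, in seconds from ``cycle_start``."""

    t_P: float
    t_Q: float
    t_R: float
    t_S: float
    t_T: float
    cycle_length: float
    cycle_start: float = 0.0

    def __post_init__(self):
        seq = (self.t_P, self.t_Q, self.t_R, self.t_S, self.t_T, self.cycle_length)
        if not all(math.isfinite(v) for v in seq):
            raise ValueError("fiducial times must be finite")
        if not (0.0 <= self.t_P < self.t_Q < self.t_R < self.t_S < self.t_T < self.cycle_length):
            raise ValueError(
                "fiducials must satisfy 0 <= t_P < t_Q < t_R < t_S < t_T < cycle_length, "
                f"got {seq}"
            )


@dataclass(frozen=True)
class ActivationTiming:
    """Per-cycle compliance activation parameters.

    T_a    atrial activation onset (s)
    d_la   left-atrial activation delay (s)
    d      ventricular activation delay (s)
    T1     systolic activation instant (s)
    T2     diastolic activation instant (s)
    T      cycle length (s)
    """

    T_a: float
    d_la: float
    d: float
    T1: float
    T2: float
    T: float

    def __post_init__(self):
        if not (0.0 <= self.T_a < self.T):
            raise ValueError(f"need 0 <= T_a < T, got T_a={self.T_a}, T={self.T}")
        if self.T_a > self.d_la:
            raise ValueError(f"need T_a <= d_la, got {self.T_a} > {self.d_la}")
        if not (0.0 < self.T1 < self.T2 <= self.T):
            raise ValueError(f"need 0 < T1 < T2 <= T, got T1={self.T1}, T2={self.T2}, T={self.T}")
        if not (0.0 <= self.d < self.T):
            raise ValueError(f"need 0 <= d < T, got d={self.d}")


def activation_from_fiducials(f: CycleFiducials) -> ActivationTiming:
    """Map one cycle's PQRST instants to activation-timing parameters.

    T_a = t_P, d_la = (t_P + t_Q)/2, d = t_R - t_P, T1 = (t_R + t_T)/2,
    T2 = t_T, T = cycle length.
    """
    return ActivationTiming(
        T_a=f.t_P,
        d_la=0.5 * (f.t_P + f.t_Q),
        d=f.t_R - f.t_P,
        T1=0.5 * (f.t_R + f.t_T),
        T2=f.t_T,
        T=f.cycle_length,
    )


def synthesize_ecg(
    heart_rate_bpm: float,
    n_cycles: int,
    sampling_rate: float = 500.0,
    morphology: ECGMorphology | None = None,
    noise_std: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> ECGSignal:
    """Generate a clean periodic PQRST template with annotated fiducials.

    Each wave is a Gaussian bump at a fixed fraction of the cycle; the mean
    R-R interval is exactly 60/heart_rate_bpm. Optional additive white noise
    (``noise_std`` in mV) is drawn from ``rng``; the annotations always refer
    to the noise-free template.
    """
    if not (30.0 <= heart_rate_bpm <= 220.0):
        raise ValueError(f"heart_rate_bpm must be in [30, 220], got {heart_rate_bpm}")
    if n_cycles < 1 or int(n_cycles) != n_cycles:
        raise ValueError(f"n_cycles must be a positive integer, got {n_cycles}")
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be > 0, got {sampling_rate}")
    morphology = morphology or ECGMorphology()
    morphology.validate()

    T = 60.0 / heart_rate_bpm
    n = int(round(n_cycles * T * sampling_rate))
    t = np.arange(n) / sampling_rate
    x = np.zeros(n)
    annotations: dict[str, np.ndarray] = {}
    for wave in ("P", "Q", "R", "S", "T"):
        centers = (np.arange(n_cycles) + morphology.positions[wave]) * T
        width = morphology.widths[wave] * T
        for c in centers:
            x += morphology.amplitudes[wave] * np.exp(-0.5 * ((t - c) / width) ** 2)
        annotations[wave] = centers
    if noise_std > 0.0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        x = x + gen.normal(0.0, noise_std, size=n)
    return ECGSignal(samples=x, sampling_rate=sampling_rate, annotations=annotations)


def _detect_r_peaks(ecg: ECGSignal, threshold_frac: float = 0.6) -> np.ndarray:
    """Local maxima above an adaptive threshold (fraction of a rolling max).

    The rolling window spans roughly two expected cycles so the threshold
    tracks slow amplitude drift without swallowing genuine peaks.
    """
    x = ecg.samples
    n = x.size
    if n < 3:
        raise FiducialDetectionError("signal too short for R-peak detection")
    # centred rolling maximum spanning ~2.2 s either side, so every sample's
    # window contains at least one R peak for any plausible heart rate
    window = 2 * max(int(2.2 * ecg.sampling_rate), 1) + 1
    rolling = maximum_filter1d(x, size=window, mode="nearest")
    threshold = threshold_frac * np.maximum(rolling, 1e-12)

    is_peak = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]) & (x[1:-1] >= threshold[1:-1]) & (x[1:-1] > 0)
    candidates = np.flatnonzero(is_peak) + 1
    if candidates.size == 0:
        raise FiducialDetectionError("no R peaks found (flat or sub-threshold signal)")
    # enforce a refractory period of 0.2 s, keeping the taller peak
    refractory = int(0.2 * ecg.sampling_rate)
    peaks: list[int] = []
    for idx in candidates:
        if peaks and idx - peaks[-1] < refractory:
            if x[idx] > x[peaks[-1]]:
                peaks[-1] = idx
        else:
            peaks.append(idx)
    if len(peaks) < 2:
        raise FiducialDetectionError(f"need >= 2 R peaks, found {len(peaks)}")
    return np.asarray(peaks)


def _extremum(x: np.ndarray, lo: int, hi: int, sign: float) -> int:
    lo = max(lo, 0)
    hi = min(hi, x.size)
    if hi <= lo:
        raise FiducialDetectionError("empty fiducial search window")
    seg = sign * x[lo:hi]
    return lo + int(np.argmax(seg))


def detect_fiducials(ecg: ECGSignal, r_frac: float = DEFAULT_R_FRACTION) -> list[CycleFiducials]:
    """Locate PQRST instants per R-R-delimited cycle.

    P/Q/S/T are signed extrema in windows placed relative to each R peak;
    the first partial cycle (before the first R-R interval) is discarded, so
    a signal with n R peaks yields n-1 cycles. Cycle i is anchored at
    ``R_i - r_frac * RR_i`` with length ``RR_i = R_i - R_{i-1}``.
    """
    if not np.all(np.isfinite(ecg.samples)):
        raise ValueError("ECG samples must be finite")
    fs = ecg.sampling_rate
    x = ecg.samples
    r_peaks = _detect_r_peaks(ecg)
    cycles: list[CycleFiducials] = []
    for i in range(1, r_peaks.size):
        rr = (r_peaks[i] - r_peaks[i - 1]) / fs
        r_idx = r_peaks[i]
        w = lambda frac: int(round(frac * rr * fs))  # noqa: E731
        p_idx = _extremum(x, r_idx - w(0.25), r_idx - w(0.05), +1.0)
        q_idx = _extremum(x, r_idx - w(0.07), r_idx - max(w(0.01), 1), -1.0)
        s_idx = _extremum(x, r_idx + max(w(0.01), 1), r_idx + w(0.08), -1.0)
        t_idx = _extremum(x, r_idx + w(0.15), r_idx + w(0.45), +1.0)
        start = r_idx / fs - r_frac * rr
        try:
            cycles.append(
                CycleFiducials(
                    t_P=p_idx / fs - start,
                    t_Q=q_idx / fs - start,
                    t_R=r_idx / fs - start,
                    t_S=s_idx / fs - start,
                    t_T=t_idx / fs - start,
                    cycle_length=rr,
                    cycle_start=start,
                )
            )
        except ValueError as exc:
            raise FiducialDetectionError(f"cycle {i}: implausible fiducial ordering ({exc})")
    if not cycles:
        raise FiducialDetectionError("no complete cardiac cycle detected")
    return cycles


def cycles_from_annotations(
    ecg: ECGSignal, r_frac: float = DEFAULT_R_FRACTION
) -> list[CycleFiducials]:
    """Build CycleFiducials from a synthetic signal's ground-truth annotations,
    using the same cycle-anchor convention as :func:`detect_fiducials`."""
    if not ecg.annotations:
        raise ValueError("signal carries no annotations")
    ann = ecg.annotations
    r_times = np.asarray(ann["R"], dtype=float)
    cycles = []
    for i in range(1, r_times.size):
        rr = r_times[i] - r_times[i - 1]
        start = r_times[i] - r_frac * rr
        cycles.append(
            CycleFiducials(
                t_P=ann["P"][i] - start,
                t_Q=ann["Q"][i] - start,
                t_R=ann["R"][i] - start,
                t_S=ann["S"][i] - start,
                t_T=ann["T"][i] - start,
                cycle_length=rr,
                cycle_start=start,
            )
        )
    return cycles


def load_ecg_csv(path, sampling_rate: float) -> ECGSignal:
    """Read a single-column CSV of ECG samples (header optional)."""
    raw = np.genfromtxt(path, delimiter=",")
    raw = np.atleast_1d(raw.squeeze())
    if raw.ndim != 1:
        raise ValueError("expected a single-column CSV of samples")
    if raw.size and np.isnan(raw[0]):  # header row became NaN
        raw = raw[1:]
    return ECGSignal(samples=raw, sampling_rate=sampling_rate)
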