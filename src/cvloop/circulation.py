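"""Closed-loop six-compartment pressure dynamics.

The circulation is a loop of compliance compartments (la, lv, sa, ra, rv,
pa) joined by resistive paths. Four diode-like valves (mitral, aortic,
tricuspid, pulmonic) switch on the instantaneous pressure difference: a
valve passes flow freely when its upstream pressure exceeds the downstream
one and otherwise passes only the leak fraction ``delta`` of the reverse
gradient. The resulting regime-switching ODE in the six pressures is
integrated with fixed-step classical RK4; chamber volumes are reconstructed
algebraically from V = C(t) P + V_s.

Ordering convention for the state vector: (P_la, P_lv, P_sa, P_ra, P_rv,
P_pa), matching :class:`HemodynamicState`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import compliance as cm
from .ecg import ActivationTiming

__all__ = [
    "CirculationParameters",
    "ValveConfiguration",
    "HemodynamicState",
    "SimulationResult",
    "NumericalFailure",
    "valve_control",
    "pressure_derivatives",
    "simulate",
    "detect_steady_state",
    "segment_phases",
    "total_blood_volume",
    "PRESSURE_KEYS",
]

PRESSURE_KEYS = ("la", "lv", "sa", "ra", "rv", "pa")
CHAMBER_KEYS = ("la", "lv", "ra", "rv")
FLOW_KEYS = ("mi", "ao", "tr", "pu", "s", "p")


class NumericalFailure(RuntimeError):
    """Integration produced a non-finite state."""


@dataclass(frozen=True)
class CirculationParameters:
    """Vascular/valvular resistances (mmHg·s/mL), arterial compliances
    (mL/mmHg), unstressed chamber volumes (mL) and initial pressures (mmHg)."""

    R_mi: float
    R_ao: float
    R_tr: float
    R_pu: float
    R_s: float
    R_p: float
    C_sa: float
    C_pa: float
    V_s: dict = field(default_factory=lambda: {"la": 5.0, "lv": 15.0, "ra": 5.0, "rv": 40.0})
    P0: dict = field(
        default_factory=lambda: {"la": 5.0, "lv": 5.0, "sa": 80.0, "ra": 5.0, "rv": 5.0, "pa": 15.0}
    )
    profile_name: str = "custom"

    def __post_init__(self):
        for name in ("R_mi", "R_ao", "R_tr", "R_pu", "R_s", "R_p", "C_sa", "C_pa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if set(self.V_s) != set(CHAMBER_KEYS):
            raise ValueError(f"V_s must have keys {CHAMBER_KEYS}")
        if any(v < 0 for v in self.V_s.values()):
            raise ValueError("unstressed volumes must be >= 0")
        if set(self.P0) != set(PRESSURE_KEYS):
            raise ValueError(f"P0 must have keys {PRESSURE_KEYS}")

    def with_mitral_resistance(self, ratio: float) -> "CirculationParameters":
        """Scaled copy: mitral resistance multiplied by ``ratio`` (disease grade)."""
        if ratio <= 0:
            raise ValueError("resistance ratio must be > 0")
        return replace(self, R_mi=self.R_mi * ratio)


@dataclass(frozen=True)
class ValveConfiguration:
    """Leak coefficients in [0, 1) per valve; all zero = healthy (pure diodes)."""

    delta_mi: float = 0.0
    delta_ao: float = 0.0
    delta_tr: float = 0.0
    delta_pu: float = 0.0

    def __post_init__(self):
        for name in ("delta_mi", "delta_ao", "delta_tr", "delta_pu"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    @property
    def healthy(self) -> bool:
        return self.delta_mi == self.delta_ao == self.delta_tr == self.delta_pu == 0.0


@dataclass(frozen=True)
class HemodynamicState:
    P_la: float
    P_lv: float
    P_sa: float
    P_ra: float
    P_rv: float
    P_pa: float

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("pressures must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.P_la, self.P_lv, self.P_sa, self.P_ra, self.P_rv, self.P_pa])


def valve_control(p_upstream: float, p_downstream: float, delta: float = 0.0) -> float:
    """Valve opening: 1 if the upstream pressure strictly exceeds the
    downstream one, else the leak coefficient ``delta`` (ties -> closed)."""
    if not (np.isfinite(p_upstream) and np.isfinite(p_downstream)):
        raise ValueError("pressures must be finite")
    if not (0.0 <= delta < 1.0):
        raise ValueError(f"delta must be in [0, 1), got {delta}")
    return 1.0 if p_upstream > p_downstream else delta


def pressure_derivatives(
    state,
    t: float,
    params: CirculationParameters,
    valves: ValveConfiguration,
    compliance_params: cm.ComplianceParameters,
    timing: ActivationTiming,
) -> np.ndarray:
    """Right-hand side of the six pressure ODEs at cycle time ``t``.

    ``state`` may be a :class:`HemodynamicState` or a length-6 array in the
    (la, lv, sa, ra, rv, pa) order. Chamber compliances and their rates are
    evaluated from the compliance module at ``t``.
    """
    y = state.as_array() if isinstance(state, HemodynamicState) else np.asarray(state, dtype=float)
    P_la, P_lv, P_sa, P_ra, P_rv, P_pa = y
    C = {ch: cm.compliance(t, ch, compliance_params, timing) for ch in CHAMBER_KEYS}
    dC = {ch: cm.compliance_derivative(t, ch, compliance_params, timing) for ch in CHAMBER_KEYS}
    if any(C[ch] <= 0 for ch in CHAMBER_KEYS):
        raise NumericalFailure(f"non-positive chamber compliance at t={t}")
    U_mi = valve_control(P_la, P_lv, valves.delta_mi)
    U_ao = valve_control(P_lv, P_sa, valves.delta_ao)
    U_tr = valve_control(P_ra, P_rv, valves.delta_tr)
    U_pu = valve_control(P_rv, P_pa, valves.delta_pu)
    Q_mi = U_mi * (P_la - P_lv) / params.R_mi
    Q_ao = U_ao * (P_lv - P_sa) / params.R_ao
    Q_tr = U_tr * (P_ra - P_rv) / params.R_tr
    Q_pu = U_pu * (P_rv - P_pa) / params.R_pu
    Q_s = (P_sa - P_ra) / params.R_s
    Q_p = (P_pa - P_la) / params.R_p
    return np.array(
        [
            (Q_p - Q_mi - dC["la"] * P_la) / C["la"],
            (Q_mi - Q_ao - dC["lv"] * P_lv) / C["lv"],
            (Q_ao - Q_s) / params.C_sa,
            (Q_s - Q_tr - dC["ra"] * P_ra) / C["ra"],
            (Q_tr - Q_pu - dC["rv"] * P_rv) / C["rv"],
            (Q_pu - Q_p) / params.C_pa,
        ]
    )


@dataclass
class SimulationResult:
    """Dense simulation output on a uniform time grid.

    pressures/volumes/valve_states/flows are dicts of equal-length arrays;
    ``cycle_index`` gives, per output sample, which timing cycle it belongs
    to, and ``cycle_starts`` the output index at which each cycle begins.
    ``ppg`` is filled by the ppg module.
    """

    time: np.ndarray
    pressures: dict
    volumes: dict
    valve_states: dict
    flows: dict
    cycle_starts: np.ndarray
    cycle_index: np.ndarray
    timing: list
    params: CirculationParameters
    valves: ValveConfiguration
    compliance_params: cm.ComplianceParameters
    dt: float
    ppg: np.ndarray | None = None
    steady_state_cycle_index: int | None = None
    converged: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.timing)

    def cycle_slice(self, k: int) -> slice:
        """Output-sample slice of cycle ``k`` (half-open)."""
        if not 0 <= k < self.n_cycles:
            raise IndexError(f"cycle {k} out of range (0..{self.n_cycles - 1})")
        start = self.cycle_starts[k]
        stop = self.cycle_starts[k + 1] if k + 1 < self.n_cycles else self.time.size
        return slice(int(start), int(stop))


def _compliance_tables(compliance_params, timing, n_steps, dt):
    """C and dC/dt for all four chambers on the half-step grid of one cycle."""
    t_half = np.arange(2 * n_steps + 1) * (0.5 * dt)
    tabs = {}
    for ch in CHAMBER_KEYS:
        tabs[ch] = (
            np.asarray(cm.compliance(t_half, ch, compliance_params, timing), dtype=float),
            np.asarray(cm.compliance_derivative(t_half, ch, compliance_params, timing), dtype=float),
        )
    return tabs


def simulate(
    params: CirculationParameters,
    valves: ValveConfiguration,
    compliance_params: cm.ComplianceParameters,
    timing,
    n_cycles: int | None = None,
    duration: float | None = None,
    dt: float = 1e-4,
    output_stride: int = 10,
    steady_tol: float = 1e-3,
) -> SimulationResult:
    """Integrate the closed loop over a sequence of cardiac cycles.

    ``timing`` is an :class:`ActivationTiming` or a list of them (one per
    cycle; a short list is extended by repeating its last element). Exactly
    one of ``n_cycles``/``duration`` may be given when ``timing`` is a single
    object; with a list, its length sets the default cycle count. Output is
    decimated by ``output_stride`` relative to the integration step ``dt``.
    Steady state is flagged at the first cycle whose lv pressure-volume loop
    is within ``steady_tol`` (range-normalised max-norm) of the previous one.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if output_stride < 1:
        raise ValueError("output_stride must be >= 1")
    if isinstance(timing, ActivationTiming):
        timings = [timing]
    else:
        timings = list(timing)
    if not timings:
        raise ValueError("need at least one ActivationTiming cycle")
    if n_cycles is None:
        if duration is not None:
            n_cycles = max(1, int(np.ceil(duration / timings[-1].T)))
        else:
            n_cycles = len(timings)
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    while len(timings) < n_cycles:
        timings.append(timings[-1])
    timings = timings[:n_cycles]

    R_mi, R_ao, R_tr, R_pu = params.R_mi, params.R_ao, params.R_tr, params.R_pu
    R_s, R_p, C_sa, C_pa = params.R_s, params.R_p, params.C_sa, params.C_pa
    d_mi, d_ao = valves.delta_mi, valves.delta_ao
    d_tr, d_pu = valves.delta_tr, valves.delta_pu

    y = [params.P0[k] for k in PRESSURE_KEYS]
    out = [np.array(y)]
    out_times = [0.0]
    cycle_starts = [0]
    table_cache: dict = {}
    t_global = 0.0

    for k, tk in enumerate(timings):
        n_steps = int(round(tk.T / dt))
        if n_steps < 2:
            raise ValueError(f"dt={dt} too coarse for cycle length {tk.T}")
        key = (tk, n_steps)
        if key not in table_cache:
            table_cache[key] = _compliance_tables(compliance_params, tk, n_steps, dt)
        tabs = table_cache[key]
        Cla, dCla = tabs["la"]
        Clv, dClv = tabs["lv"]
        Cra, dCra = tabs["ra"]
        Crv, dCrv = tabs["rv"]
        if min(Cla.min(), Clv.min(), Cra.min(), Crv.min()) <= 0.0:
            raise NumericalFailure("non-positive chamber compliance in tables")

        def rhs(j, s):
            P_la, P_lv, P_sa, P_ra, P_rv, P_pa = s
            Q_mi = ((1.0 if P_la > P_lv else d_mi) * (P_la - P_lv)) / R_mi
            Q_ao = ((1.0 if P_lv > P_sa else d_ao) * (P_lv - P_sa)) / R_ao
            Q_tr = ((1.0 if P_ra > P_rv else d_tr) * (P_ra - P_rv)) / R_tr
            Q_pu = ((1.0 if P_rv > P_pa else d_pu) * (P_rv - P_pa)) / R_pu
            Q_s = (P_sa - P_ra) / R_s
            Q_p = (P_pa - P_la) / R_p
            return (
                (Q_p - Q_mi - dCla[j] * P_la) / Cla[j],
                (Q_mi - Q_ao - dClv[j] * P_lv) / Clv[j],
                (Q_ao - Q_s) / C_sa,
                (Q_s - Q_tr - dCra[j] * P_ra) / Cra[j],
                (Q_tr - Q_pu - dCrv[j] * P_rv) / Crv[j],
                (Q_pu - Q_p) / C_pa,
            )

        half = 0.5 * dt
        sixth = dt / 6.0
        for i in range(n_steps):
            j0 = 2 * i
            k1 = rhs(j0, y)
            y1 = [y[m] + half * k1[m] for m in range(6)]
            k2 = rhs(j0 + 1, y1)
            y2 = [y[m] + half * k2[m] for m in range(6)]
            k3 = rhs(j0 + 1, y2)
            y3 = [y[m] + dt * k3[m] for m in range(6)]
            k4 = rhs(j0 + 2, y3)
            y = [
                y[m] + sixth * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m]) for m in range(6)
            ]
            if (i + 1) % output_stride == 0:
                out.append(np.array(y))
                out_times.append(t_global + (i + 1) * dt)
        if not all(np.isfinite(v) for v in y):
            raise NumericalFailure(
                f"non-finite state after cycle {k}: {dict(zip(PRESSURE_KEYS, y))}"
            )
        t_global += n_steps * dt
        if k + 1 < n_cycles:
            cycle_starts.append(len(out) - 1 if (n_steps % output_stride == 0) else len(out))
        # next cycle continues from current y

    time = np.asarray(out_times)
    P = np.vstack(out)
    pressures = {key: P[:, m] for m, key in enumerate(PRESSURE_KEYS)}

    # cycle membership per output sample (first sample of each cycle is its start)
    cycle_starts_arr = np.asarray(cycle_starts, dtype=int)
    cycle_index = np.zeros(time.size, dtype=int)
    for k in range(1, len(cycle_starts)):
        cycle_index[cycle_starts_arr[k]:] = k

    # reconstruct volumes and flows on the output grid
    volumes = {}
    for ch in CHAMBER_KEYS:
        C_tr = np.empty(time.size)
        for k in range(n_cycles):
            tk = timings[k]
            sl = slice(
                cycle_starts_arr[k],
                cycle_starts_arr[k + 1] if k + 1 < n_cycles else time.size,
            )
            local_t = cm._wrap(time[sl] - time[cycle_starts_arr[k]], tk.T)
            C_tr[sl] = cm.compliance(local_t, ch, compliance_params, tk)
        volumes[ch] = C_tr * pressures[ch] + params.V_s[ch]

    U_mi = np.where(pressures["la"] > pressures["lv"], 1.0, d_mi)
    U_ao = np.where(pressures["lv"] > pressures["sa"], 1.0, d_ao)
    U_tr = np.where(pressures["ra"] > pressures["rv"], 1.0, d_tr)
    U_pu = np.where(pressures["rv"] > pressures["pa"], 1.0, d_pu)
    valve_states = {"mi": U_mi, "ao": U_ao, "tr": U_tr, "pu": U_pu}
    flows = {
        "mi": U_mi * (pressures["la"] - pressures["lv"]) / R_mi,
        "ao": U_ao * (pressures["lv"] - pressures["sa"]) / R_ao,
        "tr": U_tr * (pressures["ra"] - pressures["rv"]) / R_tr,
        "pu": U_pu * (pressures["rv"] - pressures["pa"]) / R_pu,
        "s": (pressures["sa"] - pressures["ra"]) / R_s,
        "p": (pressures["pa"] - pressures["la"]) / R_p,
    }

    result = SimulationResult(
        time=time,
        pressures=pressures,
        volumes=volumes,
        valve_states=valve_states,
        flows=flows,
        cycle_starts=cycle_starts_arr,
        cycle_index=cycle_index,
        timing=timings,
        params=params,
        valves=valves,
        compliance_params=compliance_params,
        dt=dt,
    )
    idx, converged = detect_steady_state(result, tol=steady_tol)
    result.steady_state_cycle_index = idx
    result.converged = converged
    return result


def _cycle_loop(result: SimulationResult, k: int, n_phase: int = 400):
    """lv pressure and volume of cycle k resampled on a common phase grid."""
    sl = result.cycle_slice(k)
    t = result.time[sl]
    if t.size < 3:
        raise ValueError("cycle too short for loop comparison")
    phase = (t - t[0]) / (result.timing[k].T)
    grid = np.linspace(0.0, 1.0, n_phase, endpoint=False)
    p = np.interp(grid, phase, result.pressures["lv"][sl])
    v = np.interp(grid, phase, result.volumes["lv"][sl])
    return p, v


def detect_steady_state(result: SimulationResult, tol: float = 1e-3):
    """First cycle whose lv PV loop is within ``tol`` of the previous cycle.

    Distance is the max over pressure and volume of the max-norm difference
    normalised by that signal's range over the two cycles. Returns
    ``(cycle_index, converged)``; when no cycle converges the last cycle
    index is returned with ``converged=False``.
    """
    n = result.n_cycles
    if n < 2:
        return n - 1, False
    prev = _cycle_loop(result, 0)
    for k in range(1, n):
        cur = _cycle_loop(result, k)
        dist = 0.0
        for a, b in zip(prev, cur):
            rng = max(np.max(a), np.max(b)) - min(np.min(a), np.min(b))
            rng = max(rng, 1e-9)
            dist = max(dist, float(np.max(np.abs(a - b))) / rng)
        if dist < tol:
            return k, True
        prev = cur
    return n - 1, False


def steady_state_distances(result: SimulationResult) -> np.ndarray:
    """Loop-to-previous-loop distances per cycle (diagnostic for convergence)."""
    n = result.n_cycles
    dists = np.full(n, np.nan)
    prev = _cycle_loop(result, 0)
    for k in range(1, n):
        cur = _cycle_loop(result, k)
        dist = 0.0
        for a, b in zip(prev, cur):
            rng = max(np.max(a), np.max(b)) - min(np.min(a), np.min(b))
            dist = max(dist, float(np.max(np.abs(a - b))) / max(rng, 1e-9))
        dists[k] = dist
        prev = cur
    return dists


@dataclass(frozen=True)
class CyclePhases:
    """Left-heart phase intervals of one physiological cycle.

    Intervals are (t_start, t_end) in absolute simulation time, keyed
    'I' (isovolumetric relaxation), 'II' (filling), 'III' (isovolumetric
    contraction), 'IV' (ejection). ``edv``/``esv`` are the lv volumes at the
    II->III and IV->I boundaries. ``no_isovolumetric`` flags loops whose
    isovolumetric intervals have (near-)vanished, as under significant
    mitral regurgitation.
    """

    intervals: dict
    edv: float
    esv: float
    edv_time: float
    esv_time: float
    no_isovolumetric: bool


def segment_phases(result: SimulationResult, cycle: int, iso_threshold: float = 0.01) -> CyclePhases:
    """Partition one steady cycle into the four left-heart phases.

    The physiological cycle is delimited by consecutive aortic-valve
    closures (ejection end): I runs until the mitral valve opens, II until
    it closes, III until the aortic valve opens, IV until it closes again.
    ``cycle`` indexes the timing cycle whose start the window is anchored
    to; the window must be followed by one more simulated cycle.
    """
    if cycle + 1 >= result.n_cycles:
        raise ValueError("phase segmentation needs the following cycle in the record")
    sl = slice(result.cycle_slice(cycle).start, result.cycle_slice(cycle + 1).stop)
    t = result.time[sl]
    mi_open = result.valve_states["mi"][sl] == 1.0
    ao_open = result.valve_states["ao"][sl] == 1.0
    v_lv = result.volumes["lv"][sl]

    ao_close = np.flatnonzero(ao_open[:-1] & ~ao_open[1:]) + 1
    if ao_close.size < 2:
        raise ValueError("no complete ejection cycle found in window")
    a, b = int(ao_close[0]), int(ao_close[1])

    mi_open_idx = np.flatnonzero(mi_open[a:b]) + a
    if mi_open_idx.size == 0:
        raise ValueError("mitral valve never opens within the cycle")
    ii_start = int(mi_open_idx[0])
    ii_end = int(mi_open_idx[-1]) + 1  # mitral closes here
    ao_open_idx = np.flatnonzero(ao_open[ii_end:b]) + ii_end
    iv_start = int(ao_open_idx[0]) if ao_open_idx.size else ii_end

    T = result.timing[cycle].T
    intervals = {
        "I": (float(t[a]), float(t[ii_start])),
        "II": (float(t[ii_start]), float(t[ii_end])),
        "III": (float(t[ii_end]), float(t[iv_start])),
        "IV": (float(t[iv_start]), float(t[b])),
    }
    dur_i = intervals["I"][1] - intervals["I"][0]
    dur_iii = intervals["III"][1] - intervals["III"][0]
    return CyclePhases(
        intervals=intervals,
        edv=float(v_lv[ii_end]),
        esv=float(v_lv[a]),
        edv_time=float(t[ii_end]),
        esv_time=float(t[a]),
        no_isovolumetric=(dur_i < iso_threshold * T or dur_iii < iso_threshold * T),
    )


def total_blood_volume(result: SimulationResult) -> np.ndarray:
    """Total stressed + unstressed volume over time (conservation diagnostic)."""
    v = sum(result.volumes[ch] for ch in CHAMBER_KEYS)
    v = v + result.params.C_sa * result.pressures["sa"] + result.params.C_pa * result.pressures["pa"]
    return v
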