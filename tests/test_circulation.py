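"""Valve law, pressure ODE right-hand side, integration and phase analysis."""

import math

import numpy as np
import pytest

from cvloop import compliance as cm
from cvloop.circulation import (
    CirculationParameters,
    HemodynamicState,
    ValveConfiguration,
    detect_steady_state,
    pressure_derivatives,
    segment_phases,
    simulate,
    steady_state_distances,
    total_blood_volume,
    valve_control,
)
from cvloop.ecg import ActivationTiming
from cvloop.profiles import get_profile
from cvloop.runner import RunConfiguration, run_scenario

from conftest import steady_cycle

TIMING = ActivationTiming(T_a=0.096, d_la=0.136, d=0.112, T1=0.324, T2=0.44, T=0.8)


class TestValveControl:
    def test_opens_on_forward_gradient(self):
        assert valve_control(10.0, 5.0, 0.0) == 1.0

    def test_healthy_valve_closes_tight(self):
        assert valve_control(5.0, 50.0, 0.0) == 0.0

    def test_leaky_valve_passes_delta_when_closed(self):
        assert valve_control(5.0, 50.0, 0.05) == 0.05

    def test_tie_counts_as_closed(self):
        assert valve_control(10.0, 10.0, 0.3) == 0.3

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            valve_control(np.nan, 1.0, 0.0)
        with pytest.raises(ValueError):
            valve_control(1.0, 2.0, 1.5)


def _independent_rhs(y, t, params, valves, comp, timing):
    """Hand-transcribed pressure equations, kept deliberately separate from
    the implementation: plain scalar math, no shared helpers."""
    P_la, P_lv, P_sa, P_ra, P_rv, P_pa = y

    def u_atrial(x):
        if x < timing.T_a:
            return 0.0
        return 1.0 - math.cos(2.0 * math.pi * (x - timing.T_a) / (timing.T - timing.T_a))

    def du_atrial(x):
        if x < timing.T_a:
            return 0.0
        w = 2.0 * math.pi / (timing.T - timing.T_a)
        return w * math.sin(w * (x - timing.T_a))

    def u_vent(x):
        if x < timing.T1:
            return 0.5 - 0.5 * math.cos(math.pi * x / timing.T1)
        if x < timing.T2:
            return 0.5 + 0.5 * math.cos(math.pi * (x - timing.T1) / (timing.T2 - timing.T1))
        return 0.0

    def du_vent(x):
        if x < timing.T1:
            return 0.5 * math.pi / timing.T1 * math.sin(math.pi * x / timing.T1)
        if x < timing.T2:
            return -0.5 * math.pi / (timing.T2 - timing.T1) * math.sin(
                math.pi * (x - timing.T1) / (timing.T2 - timing.T1)
            )
        return 0.0

    x_ra = t % timing.T
    x_la = (t - timing.d_la) % timing.T
    x_v = (t - timing.d) % timing.T
    C_ra = comp.C_min_ra + 0.5 * (comp.C_max_ra - comp.C_min_ra) * u_atrial(x_ra)
    dC_ra = 0.5 * (comp.C_max_ra - comp.C_min_ra) * du_atrial(x_ra)
    C_la = comp.C_min_la + 0.5 * (comp.C_max_la - comp.C_min_la) * u_atrial(x_la)
    dC_la = 0.5 * (comp.C_max_la - comp.C_min_la) * du_atrial(x_la)
    C_lv = comp.C_dia_lv - (comp.C_dia_lv - comp.C_lv) * u_vent(x_v)
    dC_lv = -(comp.C_dia_lv - comp.C_lv) * du_vent(x_v)
    C_rv = comp.C_dia_rv - (comp.C_dia_rv - comp.C_rv) * u_vent(x_v)
    dC_rv = -(comp.C_dia_rv - comp.C_rv) * du_vent(x_v)

    U_mi = 1.0 if P_la > P_lv else valves.delta_mi
    U_ao = 1.0 if P_lv > P_sa else valves.delta_ao
    U_tr = 1.0 if P_ra > P_rv else valves.delta_tr
    U_pu = 1.0 if P_rv > P_pa else valves.delta_pu
    return [
        ((P_pa - P_la) / params.R_p - U_mi * (P_la - P_lv) / params.R_mi - dC_la * P_la) / C_la,
        (U_mi * (P_la - P_lv) / params.R_mi - U_ao * (P_lv - P_sa) / params.R_ao - dC_lv * P_lv)
        / C_lv,
        (U_ao * (P_lv - P_sa) / params.R_ao - (P_sa - P_ra) / params.R_s) / params.C_sa,
        ((P_sa - P_ra) / params.R_s - U_tr * (P_ra - P_rv) / params.R_tr - dC_ra * P_ra) / C_ra,
        (U_tr * (P_ra - P_rv) / params.R_tr - U_pu * (P_rv - P_pa) / params.R_pu - dC_rv * P_rv)
        / C_rv,
        (U_pu * (P_rv - P_pa) / params.R_pu - (P_pa - P_la) / params.R_p) / params.C_pa,
    ]


class TestPressureDerivatives:
    def test_equilibrium_when_pressures_equal_and_compliances_frozen(self):
        # constant atria (C_min == C_max) and resting ventricles: dC/dt = 0,
        # equal pressures close all valves and zero every gradient
        circ, _, _, _ = get_profile("calibrated")
        comp = cm.ComplianceParameters(
            C_min_ra=3.0, C_max_ra=3.0, C_min_la=3.0, C_max_la=3.0,
            C_lv=0.2, C_rv=0.6, ventricular_mode="interpolated",
            C_dia_lv=10.0, C_dia_rv=14.0,
        )
        t_rest = TIMING.d + TIMING.T2 + 0.1  # ventricular activation zero
        state = HemodynamicState(*(20.0,) * 6)
        dy = pressure_derivatives(state, t_rest, circ, ValveConfiguration(), comp, TIMING)
        np.testing.assert_allclose(dy, 0.0, atol=1e-12)

    def test_systemic_artery_derivative_sign_follows_flow_balance(self):
        circ, comp, _, _ = get_profile("calibrated")
        state = HemodynamicState(P_la=10, P_lv=120, P_sa=100, P_ra=5, P_rv=10, P_pa=15)
        dy = pressure_derivatives(state, 0.3, circ, ValveConfiguration(), comp, TIMING)
        q_in = (120 - 100) / circ.R_ao
        q_out = (100 - 5) / circ.R_s
        assert np.sign(dy[2]) == np.sign(q_in - q_out)

    def test_agrees_with_independent_transcription_on_random_states(self):
        circ, comp, _, _ = get_profile("calibrated")
        valves = ValveConfiguration(delta_mi=0.05)
        rng = np.random.default_rng(7)
        for _ in range(100):
            y = rng.uniform([0, 0, 40, 0, 0, 5], [25, 130, 130, 20, 40, 35])
            t = rng.uniform(0.0, TIMING.T)
            got = pressure_derivatives(y, t, circ, valves, comp, TIMING)
            want = _independent_rhs(y, t, circ, valves, comp, TIMING)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-9)


class TestSimulate:
    def test_reaches_limit_cycle_within_about_five_seconds(self, healthy):
        res = healthy.result
        assert res.converged
        t_converged = res.timing[0].T * res.steady_state_cycle_index
        assert t_converged <= 5.6  # ~5 s at 75 bpm (7 cycles)

    def test_healthy_mitral_flow_is_unidirectional(self, healthy):
        assert np.all(healthy.result.flows["mi"] >= 0.0)

    def test_healthy_valve_states_are_binary(self, healthy):
        for u in healthy.result.valve_states.values():
            assert set(np.unique(u)) <= {0.0, 1.0}

    def test_total_volume_conserved_through_transient(self, healthy):
        tv = total_blood_volume(healthy.result)
        assert np.max(np.abs(tv - tv[0])) / tv[0] < 1e-3

    def test_volumes_stay_above_unstressed(self, healthy):
        res = healthy.result
        for ch, v in res.volumes.items():
            assert np.all(v >= res.params.V_s[ch] - 1e-9)

    def test_cycle_boundaries_strictly_increasing(self, healthy):
        assert np.all(np.diff(healthy.result.cycle_starts) > 0)

    def test_steady_state_periodicity(self, healthy):
        res = healthy.result
        k = steady_cycle(healthy)
        a, b = res.cycle_slice(k), res.cycle_slice(k + 1)
        n = min(a.stop - a.start, b.stop - b.start)
        for key in ("lv", "sa", "pa"):
            pa_, pb_ = res.pressures[key][a][:n], res.pressures[key][b][:n]
            assert np.max(np.abs(pa_ - pb_)) / np.ptp(pa_) < 5e-3

    def test_step_halving_changes_stroke_volume_below_half_percent(self):
        from cvloop.indices import compute_indices

        sv = {}
        for dt, stride in ((1e-4, 10), (5e-5, 20)):
            s = run_scenario(RunConfiguration(n_cycles=10, dt=dt, output_stride=stride))
            sv[dt] = s.indices.SV
        assert abs(sv[1e-4] - sv[5e-5]) / sv[5e-5] < 0.005

    def test_short_timing_list_repeats_last_cycle(self):
        circ, comp, _, _ = get_profile("calibrated")
        res = simulate(circ, ValveConfiguration(), comp, [TIMING], n_cycles=3)
        assert res.n_cycles == 3
        assert res.timing[2] == TIMING

    def test_rejects_invalid_steps(self):
        circ, comp, _, _ = get_profile("calibrated")
        with pytest.raises(ValueError):
            simulate(circ, ValveConfiguration(), comp, TIMING, n_cycles=1, dt=-1.0)


class TestSteadyStateDetection:
    def test_restart_on_limit_cycle_converges_immediately(self, healthy):
        res = healthy.result
        start = res.cycle_slice(res.n_cycles - 1).start
        p0 = {k: float(res.pressures[k][start]) for k in res.pressures}
        circ, comp, _, _ = get_profile("calibrated")
        circ = CirculationParameters(
            **{
                **{f: getattr(circ, f) for f in (
                    "R_mi", "R_ao", "R_tr", "R_pu", "R_s", "R_p", "C_sa", "C_pa")},
                "V_s": circ.V_s,
                "P0": p0,
                "profile_name": "restart",
            }
        )
        res2 = simulate(circ, ValveConfiguration(), comp, res.timing[0], n_cycles=4)
        idx, converged = detect_steady_state(res2)
        assert converged and idx == 1

    def test_distances_contract_after_transient(self, healthy):
        # loop-to-loop distance decays geometrically once the fast arterial
        # transient has passed; small per-cycle wiggle is tolerated
        d = steady_state_distances(healthy.result)
        k = healthy.result.steady_state_cycle_index
        seq = d[2 : k + 1]
        assert np.all(seq[1:] <= 1.2 * seq[:-1])
        assert seq[-1] < 0.1 * seq[0]


class TestPhases:
    def test_healthy_cycle_has_four_ordered_phases(self, healthy):
        ph = segment_phases(healthy.result, steady_cycle(healthy))
        assert list(ph.intervals) == ["I", "II", "III", "IV"]
        bounds = [ph.intervals[p] for p in ("I", "II", "III", "IV")]
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            assert a1 == pytest.approx(b0)
            assert a0 < a1
        assert not ph.no_isovolumetric

    def test_isovolumetric_phases_hold_lv_volume_constant(self, healthy):
        res = healthy.result
        ph = segment_phases(res, steady_cycle(healthy))
        for phase in ("I", "III"):
            t0, t1 = ph.intervals[phase]
            mask = (res.time >= t0) & (res.time <= t1)
            v = res.volumes["lv"][mask]
            assert np.ptp(v) / np.mean(v) < 0.005

    def test_edv_esv_are_volume_extrema_of_the_loop(self, healthy):
        res = healthy.result
        k = steady_cycle(healthy)
        ph = segment_phases(res, k)
        sl = res.cycle_slice(k)
        v = res.volumes["lv"][sl]
        assert ph.edv == pytest.approx(np.max(v), rel=0.01)
        assert ph.esv == pytest.approx(np.min(v), rel=0.01)

    def test_severe_mr_shrinks_isovolumetric_relaxation(self, healthy, mr_runs):
        res = mr_runs[0.05].result
        ph = segment_phases(res, steady_cycle(mr_runs[0.05]))
        T = res.timing[0].T
        dur = lambda p: ph.intervals[p][1] - ph.intervals[p][0]  # noqa: E731
        ph_h = segment_phases(healthy.result, steady_cycle(healthy))
        dur_h = lambda p: ph_h.intervals[p][1] - ph_h.intervals[p][0]  # noqa: E731
        assert dur("I") < 0.05 * T
        assert dur("I") + dur("III") < dur_h("I") + dur_h("III")
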