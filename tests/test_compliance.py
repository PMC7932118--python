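"""Activation and compliance functions: values, derivatives, periodicity."""

import numpy as np
import pytest

from cvloop.compliance import (
    ComplianceParameters,
    atrial_activation,
    atrial_compliance,
    compliance,
    compliance_derivative,
    ventricular_activation,
    ventricular_compliance,
)
from cvloop.ecg import ActivationTiming

TIMING = ActivationTiming(T_a=0.096, d_la=0.136, d=0.112, T1=0.324, T2=0.44, T=0.8)

LITERAL_PARAMS = ComplianceParameters(
    C_min_ra=0.2, C_max_ra=0.3, C_min_la=0.2, C_max_la=0.3,
    C_lv=2.5, C_rv=1.0, ventricular_mode="literal", epsilon_floor=0.05,
)
INTERP = ComplianceParameters(
    C_min_ra=3.0, C_max_ra=4.5, C_min_la=3.0, C_max_la=4.5,
    C_lv=0.2, C_rv=0.6, ventricular_mode="interpolated", C_dia_lv=10.0, C_dia_rv=14.0,
)


class TestAtrialActivation:
    def test_zero_before_onset(self):
        assert atrial_activation(0.05, TIMING.T_a, TIMING.T) == 0.0

    def test_peak_of_two_at_midpoint(self):
        mid = TIMING.T_a + (TIMING.T - TIMING.T_a) / 2
        assert atrial_activation(mid, TIMING.T_a, TIMING.T) == pytest.approx(2.0)

    def test_continuity_at_onset_and_cycle_end(self):
        eps = 1e-9
        assert atrial_activation(TIMING.T_a + eps, TIMING.T_a, TIMING.T) == pytest.approx(0.0, abs=1e-6)
        assert atrial_activation(TIMING.T - eps, TIMING.T_a, TIMING.T) == pytest.approx(0.0, abs=1e-6)

    def test_out_of_cycle_time_rejected(self):
        with pytest.raises(ValueError):
            atrial_activation(TIMING.T + 0.1, TIMING.T_a, TIMING.T)


class TestVentricularActivation:
    def test_branch_boundary_values(self):
        f = lambda t: ventricular_activation(t, TIMING.T1, TIMING.T2, TIMING.T)  # noqa: E731
        assert f(0.0) == pytest.approx(0.0)
        assert f(TIMING.T1) == pytest.approx(1.0)
        assert f(TIMING.T2) == pytest.approx(0.0)

    def test_continuity_at_branch_boundaries(self):
        eps = 1e-9
        f = lambda t: ventricular_activation(t, TIMING.T1, TIMING.T2, TIMING.T)  # noqa: E731
        assert f(TIMING.T1 - eps) == pytest.approx(f(TIMING.T1 + eps), abs=1e-6)
        assert f(TIMING.T2 - eps) == pytest.approx(f(TIMING.T2 + eps), abs=1e-6)

    def test_dense_grid_maximum_at_t1(self):
        grid = np.linspace(0.0, TIMING.T, 20001, endpoint=False)
        u = ventricular_activation(grid, TIMING.T1, TIMING.T2, TIMING.T)
        assert np.max(u) == pytest.approx(1.0, abs=1e-8)
        assert grid[int(np.argmax(u))] == pytest.approx(TIMING.T1, abs=1e-4)


class TestCompliance:
    def test_resting_atrial_value_matches_published_minimum(self):
        assert atrial_compliance(0.05, "ra", LITERAL_PARAMS, TIMING) == pytest.approx(0.2)

    def test_peak_atrial_value_is_maximum(self):
        mid = TIMING.T_a + (TIMING.T - TIMING.T_a) / 2
        assert atrial_compliance(mid, "ra", LITERAL_PARAMS, TIMING) == pytest.approx(0.3)

    def test_la_trace_is_delayed_ra_trace(self):
        grid = np.linspace(0.0, TIMING.T, 400, endpoint=False)
        ra = atrial_compliance(grid, "ra", LITERAL_PARAMS, TIMING)
        la = atrial_compliance(np.mod(grid + TIMING.d_la, TIMING.T), "la", LITERAL_PARAMS, TIMING)
        np.testing.assert_allclose(la, ra, atol=1e-12)

    def test_interpolated_mode_endpoints(self):
        # u_v = 0 well after T2 (diastole) and u_v = 1 at the systolic peak
        t_dia = TIMING.d + TIMING.T2 + 0.1
        t_sys = TIMING.d + TIMING.T1
        assert ventricular_compliance(t_dia, "lv", INTERP, TIMING) == pytest.approx(10.0)
        assert ventricular_compliance(t_sys, "lv", INTERP, TIMING) == pytest.approx(0.2)

    def test_literal_mode_floors_at_epsilon(self):
        t_dia = TIMING.d + TIMING.T2 + 0.1
        assert ventricular_compliance(t_dia, "lv", LITERAL_PARAMS, TIMING) == LITERAL_PARAMS.epsilon_floor

    def test_bounded_by_declared_extrema(self):
        grid = np.linspace(0.0, TIMING.T, 4000, endpoint=False)
        for ch, lo, hi in [("ra", 3.0, 4.5), ("la", 3.0, 4.5), ("lv", 0.2, 10.0), ("rv", 0.6, 14.0)]:
            c = compliance(grid, ch, INTERP, TIMING)
            assert np.all(c >= lo - 1e-12) and np.all(c <= hi + 1e-12)

    def test_interpolated_requires_diastolic_values(self):
        with pytest.raises(ValueError):
            ComplianceParameters(
                C_min_ra=1, C_max_ra=2, C_min_la=1, C_max_la=2, C_lv=0.2, C_rv=0.6,
                ventricular_mode="interpolated",
            )


class TestDerivative:
    def test_zero_on_constant_branches(self):
        assert compliance_derivative(0.05, "ra", LITERAL_PARAMS, TIMING) == 0.0
        t_after = TIMING.d + TIMING.T2 + 0.05  # ventricular resting branch
        assert compliance_derivative(t_after, "lv", INTERP, TIMING) == 0.0

    @pytest.mark.parametrize("chamber", ["ra", "la", "lv", "rv"])
    def test_matches_central_finite_difference(self, chamber):
        rng = np.random.default_rng(42)
        h = 1e-6
        # sample interior points away from branch kinks by a safe margin
        margin = 1e-3
        kinks = np.array(
            [0.0, TIMING.T_a, TIMING.d_la, TIMING.d, TIMING.d + TIMING.T1,
             TIMING.d + TIMING.T2, TIMING.T_a + TIMING.d_la, TIMING.T]
        )
        pts = []
        while len(pts) < 1000:
            t = rng.uniform(margin, TIMING.T - margin)
            if np.min(np.abs(t - kinks)) > margin:
                pts.append(t)
        pts = np.array(pts)
        analytic = np.asarray(compliance_derivative(pts, chamber, INTERP, TIMING))
        fd = (
            np.asarray(compliance(pts + h, chamber, INTERP, TIMING))
            - np.asarray(compliance(pts - h, chamber, INTERP, TIMING))
        ) / (2 * h)
        scale = np.maximum(np.abs(analytic), np.max(np.abs(analytic)))
        np.testing.assert_array_less(np.abs(analytic - fd), 1e-6 * scale + 1e-9)

    @pytest.mark.parametrize("chamber", ["ra", "la", "lv", "rv"])
    def test_integral_over_cycle_vanishes(self, chamber):
        # periodic C(t): the closed-period integral of dC/dt must be ~0
        grid = np.linspace(0.0, TIMING.T, 200001)  # includes t=T (wraps to 0)
        dc = np.asarray(compliance_derivative(grid, chamber, INTERP, TIMING))
        integral = np.trapezoid(dc, grid)
        c_max = np.max(np.asarray(compliance(grid, chamber, INTERP, TIMING)))
        assert abs(integral) < 1e-6 * c_max

    def test_periodicity_of_traces(self):
        grid = np.linspace(0.0, TIMING.T, 1000, endpoint=False)
        for ch in ("ra", "la", "lv", "rv"):
            a = np.asarray(compliance(grid, ch, INTERP, TIMING))
            b = np.asarray(compliance(np.mod(grid + TIMING.T, TIMING.T), ch, INTERP, TIMING))
            np.testing.assert_allclose(a, b, atol=1e-12)
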