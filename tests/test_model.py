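"""Closed-form layer: feedback shape, forcing, vector field, local analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import calcalk as ck


class TestSigmoid:
    def test_midpoint_is_zero(self):
        assert ck.sigmoid_feedback(2.0, 2.0, 0.1) == 0.0

    def test_printed_formula_value(self):
        # (2/pi) arctan(pi/2) at one scale-length above the midpoint
        expected = (2.0 / math.pi) * math.atan(math.pi / 2.0)
        assert ck.sigmoid_feedback(2.1, 2.0, 0.1) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.6390, abs=1e-4)

    def test_limits_and_bounds(self):
        A = np.linspace(-50, 50, 1001)
        S = ck.sigmoid_feedback(A, 2.0, 0.1)
        assert np.all(np.abs(S) < 1.0)
        assert ck.sigmoid_feedback(1e12) == pytest.approx(1.0, abs=1e-10)
        assert ck.sigmoid_feedback(-1e12) == pytest.approx(-1.0, abs=1e-10)
        assert np.all(np.diff(S) > 0), "strictly increasing"

    @settings(derandomize=True, max_examples=50)
    @given(dA=st.floats(-20, 20, allow_nan=False),
           z0=st.floats(0.01, 10.0))
    def test_odd_about_midpoint_and_slope(self, dA, z0):
        A0 = 2.0
        up = ck.sigmoid_feedback(A0 + dA, A0, z0)
        dn = ck.sigmoid_feedback(A0 - dA, A0, z0)
        assert up == pytest.approx(-dn, abs=1e-12)
        h = 1e-6 * z0
        slope = (ck.sigmoid_feedback(A0 + h, A0, z0)
                 - ck.sigmoid_feedback(A0 - h, A0, z0)) / (2 * h)
        assert slope == pytest.approx(1.0 / z0, rel=1e-6)
        assert ck.sigmoid_slope(A0, A0, z0) == pytest.approx(1.0 / z0, rel=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ck.sigmoid_feedback(2.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            ck.sigmoid_slope(2.0, 2.0, -0.1)


class TestForcing:
    def test_phase_and_extremes(self, defaults):
        p = defaults.with_(alpha=0.003)
        assert ck.forcing_rate(0.0, p) == pytest.approx(0.05015, rel=1e-12)
        assert ck.forcing_rate(p.T_force / 2, p) == pytest.approx(0.05 * 0.997, rel=1e-9)
        t = np.linspace(0, 5 * p.T_force, 1000)
        k = ck.forcing_rate(t, p)
        assert np.all(k >= 0.05 * (1 - 0.003) - 1e-15)
        assert np.all(k <= 0.05 * (1 + 0.003) + 1e-15)

    def test_unforced_is_constant(self, defaults):
        t = np.linspace(0, 1e6, 100)
        assert np.all(ck.forcing_rate(t, defaults) == 0.05)

    def test_zero_weight_component_is_identity(self, defaults):
        p1 = defaults.with_(alpha=0.003)
        p2 = defaults.with_(alpha=0.003, extra_forcing=((0.0, 2e4, 0.0),))
        t = np.linspace(0, 1e6, 500)
        assert np.array_equal(ck.forcing_rate(t, p1), ck.forcing_rate(t, p2))


class TestGammaSchedule:
    def test_step_before_and_after(self):
        s = ck.GammaSchedule.step(0.06, 0.09, 5e7)
        assert ck.gamma_at(4.9e7, s) == 0.06
        assert ck.gamma_at(5e7, s) == 0.09
        assert ck.gamma_at(5.1e7, s) == 0.09

    def test_ramp_midpoint_and_clamps(self):
        r = ck.GammaSchedule.ramp(0.06, 0.12, 0.0, 1e8)
        assert ck.gamma_at(5e7, r) == pytest.approx(0.09, rel=1e-12)
        assert ck.gamma_at(-1.0, r) == 0.06
        assert ck.gamma_at(2e8, r) == 0.12

    def test_zero_length_ramp_equals_step(self):
        r = ck.GammaSchedule.ramp(0.06, 0.09, 5e7, 0.0)
        s = ck.GammaSchedule.step(0.06, 0.09, 5e7)
        t = np.linspace(0, 1e8, 2001)
        assert np.array_equal(ck.gamma_at(t, r), ck.gamma_at(t, s))

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            ck.GammaSchedule("step", 0.06)          # missing gamma2/t_c
        with pytest.raises(ValueError):
            ck.GammaSchedule.constant(1.0)          # gamma >= 1
        with pytest.raises(ValueError):
            ck.GammaSchedule("ramp", 0.06, 0.09, 1e7, None)


class TestVectorField:
    def test_equilibrium_is_fixed_point(self, defaults):
        eq = ck.equilibrium(defaults, 0.0)
        assert (eq.A, eq.C) == (pytest.approx(2.0), pytest.approx(4e-5))
        assert ck.rhs(0.0, eq, defaults, 0.0) == (0.0, 0.0)
        # the midpoint kills the feedback term: gamma-independent
        dA, dP = ck.rhs(0.0, eq, defaults, 0.07)
        assert abs(dA) < 1e-20 and dP == 0.0
        assert ck.equilibrium(defaults, 0.12) == ck.equilibrium(defaults, 0.0)

    def test_change_of_variables_equivalence(self, defaults, rng):
        """(A, P) dynamics agree with the population form in (A, C = e^P)."""
        p = defaults.with_(alpha=0.003)
        for _ in range(20):
            A = rng.uniform(0.5, 3.5)
            C = rng.uniform(1e-7, 1e-3)
            t = rng.uniform(0, 1e6)
            g = rng.uniform(0, 0.12)
            dA, dP = ck.rhs(t, (A, math.log(C)), p, g)
            k = float(ck.forcing_rate(t, p))
            S = float(ck.sigmoid_feedback(A, p.A0, p.z0))
            dA_pop = p.I0 * (1 + g * S) - k * A * C
            dC_pop = k * A * C - p.M * C
            assert dA == pytest.approx(dA_pop, rel=1e-12)
            assert dP == pytest.approx(dC_pop / C, rel=1e-12)

    def test_exp_overflow_raises_diagnosable_error(self, defaults):
        with pytest.raises(ck.BlowupError):
            ck.rhs(0.0, (2.0, 800.0), defaults, 0.0)

    def test_shifted_equilibrium(self, defaults):
        p = defaults.with_(k0=0.1)  # doubled reaction rate
        eq = ck.equilibrium(p, 0.08)
        assert eq.A == pytest.approx(1.0)
        dA, dP = ck.rhs(0.0, eq, p, 0.08)
        assert max(abs(dA), abs(dP)) < 1e-12

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ck.ModelParameters(k0=-1.0)
        with pytest.raises(ValueError):
            ck.ModelParameters(alpha=1.0)
        with pytest.raises(ValueError):
            ck.ModelParameters(alpha=0.6, extra_forcing=((0.5, 2e4, 0.0),))
        with pytest.raises(ValueError):
            ck.SystemState(np.nan, 0.0)


class TestJacobian:
    def test_value_at_equilibrium(self, defaults):
        eq = ck.equilibrium(defaults, 0.0)
        J = ck.jacobian(eq, defaults, 0.0)
        np.testing.assert_allclose(J, [[-2e-6, -4e-6], [0.05, 0.0]], rtol=1e-10)

    def test_trace_and_determinant_formulas(self, defaults):
        for g in (0.0, 0.03, 0.07, 0.12):
            eq = ck.equilibrium(defaults, g)
            J = ck.jacobian(eq, defaults, g)
            tr_expected = defaults.I0 * g / defaults.z0 - defaults.k0 * defaults.I0 / defaults.M
            assert np.trace(J) == pytest.approx(tr_expected, rel=1e-10)
            assert np.linalg.det(J) == pytest.approx(2e-7, rel=1e-10)

    def test_matches_finite_differences(self, defaults, rng):
        p = defaults
        for _ in range(10):
            A = rng.uniform(0.8, 3.2)
            P = rng.uniform(-40.0, -5.0)
            g = rng.uniform(0, 0.12)
            J = ck.jacobian((A, P), p, g)
            fd = np.empty((2, 2))
            for j, h in enumerate((1e-7, 1e-7)):
                yp = [A, P]
                ym = [A, P]
                yp[j] += h
                ym[j] -= h
                fp = ck.rhs(0.0, yp, p, g)
                fm = ck.rhs(0.0, ym, p, g)
                fd[:, j] = (np.array(fp) - np.array(fm)) / (2 * h)
            scale = np.abs(J).max()
            np.testing.assert_allclose(J, fd, atol=1e-6 * scale)


class TestHopfThreshold:
    def test_reference_value(self, defaults):
        assert ck.hopf_threshold(defaults) == pytest.approx(0.05, rel=1e-12)

    def test_scaling_with_sigmoid_width(self, defaults):
        assert ck.hopf_threshold(defaults.with_(z0=0.2)) == pytest.approx(0.10, rel=1e-12)

    def test_eigenvalue_sign_crossing(self, defaults):
        g_h = ck.hopf_threshold(defaults)
        for g, sign in ((g_h - 0.005, -1), (g_h + 0.005, +1)):
            eq = ck.equilibrium(defaults, g)
            lam = np.linalg.eigvals(ck.jacobian(eq, defaults, g))
            assert sign * lam.real.max() > 0

    def test_closed_form_vs_numeric_scan(self, defaults, rng):
        """Closed form agrees with a brute-force eigenvalue-crossing scan."""
        from scipy.optimize import brentq

        for _ in range(5):
            k0 = rng.uniform(0.02, 0.2)
            M = rng.uniform(0.05, 0.3)
            z0 = rng.uniform(0.05, 0.3)
            p = defaults.with_(k0=k0, M=M, z0=z0, A0=M / k0)  # keep A* = A0

            def max_re(g, p=p):
                eq = ck.equilibrium(p, g)
                return np.linalg.eigvals(ck.jacobian(eq, p, g)).real.max()

            expected = k0 * z0 / M
            if not expected < 0.9:
                continue
            scanned = brentq(max_re, 1e-6, 0.95, xtol=1e-10)
            assert ck.hopf_threshold(p) == pytest.approx(scanned, abs=1e-6)

    def test_no_crossing_reported(self, defaults):
        # z0 huge: closed form gives gamma_H >= 1, no crossing in [0, 1)
        with pytest.raises(ValueError):
            ck.hopf_threshold(defaults.with_(z0=5.0))


class TestLinearInternalPeriod:
    def test_reference_value_is_14_kyr(self, defaults):
        T = ck.linear_internal_period(defaults, 0.0)
        omega = math.sqrt(2e-7 - (1e-6) ** 2)  # sqrt(det - tr^2/4)
        assert T == pytest.approx(2 * math.pi / omega, rel=1e-10)
        assert T / 1e3 == pytest.approx(14.0, abs=0.1)

    def test_period_halves_when_input_quadrupled(self, defaults):
        T1 = ck.linear_internal_period(defaults, 0.0)
        T4 = ck.linear_internal_period(defaults.with_(I0=4 * defaults.I0), 0.0)
        assert T4 / T1 == pytest.approx(0.5, rel=1e-4)

    def test_weak_feedback_barely_shifts_period(self, defaults):
        T0 = ck.linear_internal_period(defaults, 0.0)
        T4 = ck.linear_internal_period(defaults, 0.04)
        assert abs(T4 - T0) / T0 < 0.02

    def test_real_eigenvalues_signalled(self, defaults):
        # strong damping: M tiny makes det small vs trace -> real eigenvalues
        p = defaults.with_(I0=4e-2, z0=0.001, A0=2.0)
        with pytest.raises(ValueError):
            ck.linear_internal_period(p, 0.9)


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path, defaults):
        p = defaults.with_(alpha=0.003, extra_forcing=((0.001, 2e4, 0.5),))
        s = ck.GammaSchedule.ramp(0.06, 0.12, 5e7, 1e7)
        path = tmp_path / "cfg.yaml"
        ck.save_config(path, p, s)
        p2, s2 = ck.load_config(path)
        assert p2 == p
        assert s2 == s

    def test_defaults_preset_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        ck.save_config(path, ck.TABLE_DEFAULTS)
        p2, s2 = ck.load_config(path)
        assert p2 == ck.TABLE_DEFAULTS and s2 is None
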