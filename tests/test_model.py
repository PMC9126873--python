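"""Unit tests for the oscillator model: Hill transfer functions, the ODE
right-hand side, reactor-control algebra, nullclines and the fixed point."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zeitgeber import (CircuitState, OscillatorParams, ParameterError,
                       dilution_rate, fixed_point, hill_activation,
                       hill_repression, lambda_parameter, nullclines, ode_rhs,
                       predicted_period, refresh_for_lambda)
from zeitgeber.model import STATE_CHANNELS, effective_repressor

UNIFORM = dict(alpha=3.0, K_a=20.0, K_h=2.0, n=3.0, k_TL=0.02, tau_m=12.0)


def make_params(delta=3.1963e-4, **overrides):
    kw = {**UNIFORM, **overrides}
    return OscillatorParams.uniform(delta=delta, **kw)


class TestHillFunctions:
    @pytest.mark.parametrize("h, K, n, expected", [
        (2.0, 2.0, 3.0, 0.5),     # half-saturation
        (0.0, 2.0, 3.0, 1.0),     # no repressor
        (4.0, 2.0, 2.0, 0.2),     # 1/(1+4)
    ])
    def test_repression_values(self, h, K, n, expected):
        assert hill_repression(h, K, n) == pytest.approx(expected)

    @pytest.mark.parametrize("a, K, n, expected", [
        (20.0, 20.0, 3.0, 0.5),   # half-saturation
        (0.0, 20.0, 3.0, 0.0),    # limit at empty reactor
        (60.0, 20.0, 1.0, 0.75),  # 1/(1+1/3)
    ])
    def test_activation_values(self, a, K, n, expected):
        assert hill_activation(a, K, n) == pytest.approx(expected)

    @pytest.mark.parametrize("func", [hill_repression, hill_activation])
    @pytest.mark.parametrize("K, n", [(0.0, 2.0), (-1.0, 2.0), (2.0, 0.0), (2.0, -3.0)])
    def test_bad_parameters_rejected(self, func, K, n):
        with pytest.raises(ParameterError):
            func(1.0, K, n)

    @given(K=st.floats(1e-3, 1e3), n=st.floats(0.1, 12.0),
           lo=st.floats(0.0, 1e3), hi=st.floats(0.0, 1e3))
    def test_bounded_and_monotone(self, K, n, lo, hi):
        lo, hi = sorted((lo, hi))
        r_lo, r_hi = hill_repression(lo, K, n), hill_repression(hi, K, n)
        a_lo, a_hi = hill_activation(lo, K, n), hill_activation(hi, K, n)
        assert 0.0 <= r_hi <= r_lo <= 1.0
        assert 0.0 <= a_lo <= a_hi <= 1.0

    def test_large_hill_coefficient_is_stable(self):
        assert hill_repression(1e-12, 2.0, 8.0) == pytest.approx(1.0)
        assert hill_activation(1e-12, 20.0, 8.0) == pytest.approx(0.0)


class TestOdeRhs:
    def test_empty_reactor_production(self):
        params = make_params()
        d = ode_rhs(np.zeros(8), params)
        by_name = dict(zip(STATE_CHANNELS, d))
        assert by_name["r_a"] == pytest.approx(params.alpha_a_nM_s)
        assert by_name["r_h"] == 0.0
        for ch in ("a", "h", "rep_a", "rep_h", "x_in", "ref"):
            assert by_name[ch] == 0.0

    def test_exogenous_repressor_slows_activator_transcription(self):
        params = make_params()
        state = CircuitState(h=1.0).to_array()
        forced = CircuitState(h=1.0, x_in=5.0).to_array()
        assert (ode_rhs(forced, params, "repressor")[0]
                < ode_rhs(state, params, "repressor")[0])

    def test_inducer_sequesters_repressor(self):
        assert effective_repressor(4.0, 1.0, "inducer") == 3.0
        assert effective_repressor(1.0, 5.0, "inducer") == 0.0
        assert effective_repressor(4.0, 1.0, "repressor") == 5.0
        assert effective_repressor(4.0, 1.0, "none") == 4.0

    def test_negative_state_rejected(self):
        with pytest.raises(ParameterError):
            ode_rhs(np.full(8, -1.0), make_params())

    @given(st.lists(st.floats(0.0, 100.0), min_size=8, max_size=8),
           st.integers(0, 7))
    def test_nonnegativity_preserved_at_boundary(self, state, zero_idx):
        """Any component sitting at zero has a non-negative derivative."""
        y = np.array(state)
        y[zero_idx] = 0.0
        d = ode_rhs(y, make_params(), "none")
        assert d[zero_idx] >= 0.0

    def test_quasi_steady_state_zeroes_derivatives(self):
        # with delta << 1/tau_m the nullcline intersection is a rest point
        params = make_params(delta=1e-7)
        fp = fixed_point(params)
        d = ode_rhs(fp.to_array(), params)
        scale = params.alpha_a_nM_s
        assert np.allclose(d[:4], 0.0, atol=1e-3 * scale)


class TestReactorAlgebra:
    def test_dilution_rate_values(self):
        assert dilution_rate(0.25, 15.0) == pytest.approx(3.1963e-4, rel=1e-4)
        assert dilution_rate(1 - math.exp(-1), 15.0) == pytest.approx(1 / 900.0)

    def test_dilution_rate_monotone_and_domain(self):
        rates = [dilution_rate(R) for R in (0.05, 0.2, 0.5, 0.9)]
        assert rates == sorted(rates)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ParameterError):
                dilution_rate(bad)

    def test_lambda_parameter_value(self):
        assert lambda_parameter(0.25, 16) == pytest.approx(1.46515, rel=1e-4)

    def test_lambda_inverse_round_trip(self):
        R = refresh_for_lambda(1.20, 16)
        assert R == pytest.approx(0.2100, abs=5e-4)
        assert lambda_parameter(R, 16) == pytest.approx(1.20, rel=1e-12)

    def test_lambda_linear_in_k(self):
        assert lambda_parameter(0.3, 32) == pytest.approx(
            2 * lambda_parameter(0.3, 16))

    @given(R=st.floats(0.01, 0.95), k=st.integers(1, 64))
    def test_lambda_delta_consistency(self, R, k):
        """λ(R, k) == δ(R, t_int)·k·t_int/π exactly, for any t_int."""
        t_int = 15.0
        assert lambda_parameter(R, k) == pytest.approx(
            dilution_rate(R, t_int) * k * t_int * 60.0 / math.pi, rel=1e-12)

    def test_predicted_period(self):
        assert predicted_period(math.pi / 3600.0) == pytest.approx(1.0)
        assert predicted_period(dilution_rate(0.25)) == pytest.approx(2.73, abs=0.01)
        assert predicted_period(2 * dilution_rate(0.25)) == pytest.approx(
            predicted_period(dilution_rate(0.25)) / 2)


class TestNullclinesAndFixedPoint:
    def test_repression_free_plateau(self):
        params = make_params()
        a_curve, _ = nullclines(params, np.array([0.0]), np.array([1.0]))
        plateau = (params.alpha_a_nM_s / params.delta
                   * params.k_TL_a * params.tau_m_a_s)
        assert a_curve[0] == pytest.approx(plateau)

    def test_transcription_rate_sets_scale(self):
        params = make_params()
        doubled = make_params(alpha=2 * UNIFORM["alpha"])
        h = np.linspace(0.1, 50, 20)
        a = np.linspace(0.1, 200, 20)
        a1, h1 = nullclines(params, h, a)
        a2, h2 = nullclines(doubled, h, a)
        assert np.allclose(a2, 2 * a1)
        assert np.allclose(h2, 2 * h1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            nullclines(make_params(), np.array([]), np.array([1.0]))

    def test_fixed_point_zeroes_nullclines(self):
        from zeitgeber.model import _a_nullcline, _h_nullcline

        params = make_params()
        fp = fixed_point(params)
        assert _a_nullcline(fp.h, params) == pytest.approx(fp.a, rel=1e-8)
        assert _h_nullcline(fp.a, params) == pytest.approx(fp.h, rel=1e-8)

    def test_repressor_production_shifts_fixed_point(self):
        # stronger repressor expression pushes the rest point to higher h
        # and, through the extra repression, to lower a
        lo = fixed_point(make_params())
        hi_params = make_params().perturbed("alpha_h", 2.0)
        hi = fixed_point(hi_params)
        assert hi.h > lo.h
        assert hi.a < lo.a

    def test_vanishing_activator_production(self):
        params = make_params(alpha=1e-6)
        fp = fixed_point(params)
        assert fp.a < 1e-3 and fp.h < 1e-3


class TestParams:
    def test_positive_fields_enforced(self):
        with pytest.raises(ParameterError):
            make_params(K_a=-1.0)
        with pytest.raises(ParameterError):
            make_params(delta=0.0)

    def test_uniform_constructor_ties_pairs(self):
        p = make_params()
        assert p.alpha_a == p.alpha_h
        assert p.n_a == p.n_h
        assert p.k_TL_a == p.k_TL_h
        assert p.tau_m_a == p.tau_m_h

    def test_perturbed_unknown_name(self):
        with pytest.raises(ParameterError):
            make_params().perturbed("nonexistent", 1.3)

    def test_state_round_trip(self):
        s = CircuitState(r_a=1, a=2, r_h=3, h=4, rep_a=5, rep_h=6, x_in=7, ref=8)
        assert CircuitState.from_array(s.to_array()) == s
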