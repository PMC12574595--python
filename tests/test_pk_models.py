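"""Analytic identities and ODE cross-checks for the compartmental models."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from poppk import (
    DoseRegimen,
    ModelKind,
    PKParameters,
    conc_onecomp_abs,
    conc_onecomp_iv,
    conc_twocomp_abs,
    conc_twocomp_iv,
    predict_conc,
    twocomp_coefficients,
)
from poppk.exceptions import InvalidInputError, InvalidParameterError
from poppk.pk_models import _twocomp_abs_closed_form

IV = DoseRegimen(100.0, "iv_bolus")
ORAL = DoseRegimen(100.0, "oral")

positive = st.floats(min_value=0.1, max_value=50.0)


def params_for(kind, cl=5.0, v=50.0, v2=50.0, q=10.0, ka=1.5):
    kind = ModelKind(kind)
    kwargs = {"cl": cl, "v": v}
    if kind.is_twocomp:
        kwargs.update(v2=v2, q=q)
    if kind.has_absorption:
        kwargs["ka"] = ka
    return PKParameters(**kwargs)


class TestOneCompIV:
    def test_initial_concentration_is_dose_over_v(self):
        c = conc_onecomp_iv(PKParameters(cl=5, v=50), IV, [0.0])
        assert c[0] == pytest.approx(2.0, abs=0)

    def test_one_half_life_halves_concentration(self):
        t_half = np.log(2) * 50 / 5
        c = conc_onecomp_iv(PKParameters(cl=5, v=50), IV, [t_half])
        assert c[0] == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_at_24h(self):
        # direct scalar evaluation of (Dose/V) exp(-CL/V * t)
        c = conc_onecomp_iv(PKParameters(cl=5, v=50), IV, [24.0])
        assert c[0] == pytest.approx(2.0 * np.exp(-2.4), rel=1e-12)

    def test_strictly_decreasing(self):
        t = np.linspace(0, 48, 30)
        c = conc_onecomp_iv(PKParameters(cl=5, v=50), IV, t)
        assert np.all(np.diff(c) < 0)


class TestOneCompAbs:
    def test_zero_at_dose_time(self):
        c = conc_onecomp_abs(params_for("onecomp_abs"), ORAL, [0.0])
        assert c[0] == 0.0

    def test_tmax_matches_analytic_argmax(self):
        p = PKParameters(cl=5, v=50, ka=1.5)  # ke = 0.1
        expected = np.log(1.5 / 0.1) / (1.5 - 0.1)
        res = minimize_scalar(
            lambda t: -conc_onecomp_abs(p, ORAL, [t])[0], bounds=(0.01, 24), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.x == pytest.approx(expected, rel=1e-6)

    def test_flip_flop_limit_form(self):
        # ka -> ke: must agree with (Dose/V) ka t exp(-ka t)
        t = np.array([0.5, 2.0, 8.0, 20.0])
        p = PKParameters(cl=5.0, v=50.0, ka=0.1 + 1e-12)
        limit = (100.0 / 50.0) * 0.1 * t * np.exp(-0.1 * t)
        assert conc_onecomp_abs(p, ORAL, t) == pytest.approx(limit, rel=1e-6)

    def test_continuity_across_flip_flop_guard(self):
        t = np.array([1.0, 5.0, 15.0])
        inside = conc_onecomp_abs(PKParameters(cl=5, v=50, ka=0.1 * (1 + 5e-7)), ORAL, t)
        outside = conc_onecomp_abs(PKParameters(cl=5, v=50, ka=0.1 * (1 + 2e-6)), ORAL, t)
        assert inside == pytest.approx(outside, rel=1e-5)

    def test_single_interior_maximum(self):
        t = np.linspace(0, 24, 200)
        c = conc_onecomp_abs(params_for("onecomp_abs"), ORAL, t)
        sign_changes = np.sum(np.diff(np.sign(np.diff(c))) != 0)
        assert sign_changes == 1


class TestTwoCompCoefficients:
    def test_amplitudes_sum_to_c0(self, twocomp_truth):
        co = twocomp_coefficients(twocomp_truth, IV)
        assert co.a_coef + co.b_coef == pytest.approx(100.0 / 30.0, rel=1e-12)

    @given(cl=positive, v=positive, v2=positive, q=positive)
    def test_vieta_identities(self, cl, v, v2, q):
        p = PKParameters(cl=cl, v=v, v2=v2, q=q)
        co = twocomp_coefficients(p, IV)
        assert co.alpha * co.beta == pytest.approx(co.k10 * co.k21, rel=1e-9)
        assert co.alpha + co.beta == pytest.approx(co.k10 + co.k12 + co.k21, rel=1e-12)
        assert co.alpha >= co.beta > 0

    def test_q_to_zero_collapses_to_onecomp(self):
        t = np.linspace(0.1, 24, 15)
        p = PKParameters(cl=5, v=30, v2=50, q=1e-8)
        two = conc_twocomp_iv(p, IV, t)
        one = conc_onecomp_iv(PKParameters(cl=5, v=30), IV, t)
        assert two == pytest.approx(one, rel=1e-5)


class TestTwoCompIV:
    def test_c0_is_dose_over_v1(self, twocomp_truth):
        assert conc_twocomp_iv(twocomp_truth, IV, [0.0])[0] == pytest.approx(
            100 / 30, rel=1e-12
        )

    def test_monotone_nonincreasing(self, twocomp_truth):
        c = conc_twocomp_iv(twocomp_truth, IV, np.linspace(0, 48, 100))
        assert np.all(np.diff(c) <= 0)

    def test_against_ode_oracle_18_points(self, twocomp_truth):
        self._check_against_ode(twocomp_truth, np.linspace(0.25, 48, 18))

    def test_against_ode_oracle_random_draws(self):
        rng = np.random.default_rng(42)
        grid = np.linspace(0.05, 48, 100)
        for _ in range(50):
            cl, v, v2, q = np.exp(rng.uniform(np.log(0.5), np.log(50), 4))
            self._check_against_ode(PKParameters(cl=cl, v=v, v2=v2, q=q), grid)

    @staticmethod
    def _check_against_ode(p, times):
        k10, k12, k21 = p.cl / p.v, p.q / p.v, p.q / p.v2

        def rhs(t, y):
            ac, ap = y
            return (-(k10 + k12) * ac + k21 * ap, k12 * ac - k21 * ap)

        sol = solve_ivp(
            rhs, (0, times[-1]), (100.0, 0.0), method="LSODA",
            t_eval=times, rtol=1e-10, atol=1e-12,
        )
        oracle = sol.y[0] / p.v
        ours = conc_twocomp_iv(p, IV, times)
        # below ~1e-6 of Cmax the oracle itself is limited by its atol
        scale = np.maximum(np.abs(oracle), oracle.max() * 1e-6)
        assert np.max(np.abs(ours - oracle) / scale) < 1e-6

    def test_stiff_rate_constants_no_overflow(self):
        # k10 = 10 * k21, widely separated exponents
        p = PKParameters(cl=100.0, v=10.0, v2=100.0, q=0.1)
        c = conc_twocomp_iv(p, IV, np.linspace(0, 1000, 50))
        assert np.all(np.isfinite(c)) and np.all(c >= 0)


class TestTwoCompAbs:
    truth = PKParameters(cl=5, v=30, v2=50, q=10, ka=1.5)

    def test_zero_at_dose_time(self):
        assert conc_twocomp_abs(self.truth, ORAL, [0.0])[0] == 0.0

    def test_mass_balance(self):
        # Agut + Ac + Ap + integral(k10*Ac) must equal the dose throughout
        p = self.truth
        k10, k12, k21, ka = p.cl / p.v, p.q / p.v, p.q / p.v2, p.ka

        def rhs(t, y):
            ag, ac, ap, elim = y
            return (
                -ka * ag,
                ka * ag - (k10 + k12) * ac + k21 * ap,
                k12 * ac - k21 * ap,
                k10 * ac,
            )

        times = np.linspace(0.5, 48, 12)
        sol = solve_ivp(
            rhs, (0, 48), (100.0, 0, 0, 0), method="LSODA",
            t_eval=times, rtol=1e-10, atol=1e-12,
        )
        totals = sol.y.sum(axis=0)
        assert totals == pytest.approx(100.0, rel=1e-6)
        # and the package's concentration matches the oracle's central amount
        assert conc_twocomp_abs(p, ORAL, times) == pytest.approx(
            sol.y[1] / p.v, rel=1e-6
        )

    def test_q_to_zero_collapses_to_onecomp_abs(self):
        t = np.linspace(0.25, 24, 12)
        p = PKParameters(cl=5, v=30, v2=50, q=1e-8, ka=1.5)
        two = conc_twocomp_abs(p, ORAL, t)
        one = conc_onecomp_abs(PKParameters(cl=5, v=30, ka=1.5), ORAL, t)
        assert two == pytest.approx(one, rel=1e-5)

    def test_closed_form_matches_ode(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.1, 48, 40)
        for _ in range(20):
            cl, v, v2, q, ka = np.exp(rng.uniform(np.log(0.5), np.log(30), 5))
            p = PKParameters(cl=cl, v=v, v2=v2, q=q, ka=ka)
            ode = conc_twocomp_abs(p, ORAL, t)
            closed = _twocomp_abs_closed_form(p, ORAL, t)
            scale = np.maximum(ode, ode.max() * 1e-6)
            assert np.max(np.abs(closed - ode) / scale) < 1e-6


@pytest.mark.parametrize("kind", list(ModelKind))
class TestSharedInvariants:
    def test_finite_nonnegative_over_long_horizon(self, kind):
        p = params_for(kind)
        dose = DoseRegimen(100.0, kind.route)
        c = predict_conc(p, dose, np.geomspace(1e-3, 1e4, 50), kind)
        assert np.all(np.isfinite(c)) and np.all(c >= 0)

    def test_dose_linearity(self, kind):
        p = params_for(kind)
        t = np.linspace(0.25, 48, 12)
        c1 = predict_conc(p, DoseRegimen(100.0, kind.route), t, kind)
        c2 = predict_conc(p, DoseRegimen(200.0, kind.route), t, kind)
        assert c2 == pytest.approx(2 * c1, rel=1e-8)

    def test_output_aligns_with_input_order(self, kind):
        p = params_for(kind)
        dose = DoseRegimen(100.0, kind.route)
        t = np.array([8.0, 0.5, 24.0, 2.0])
        shuffled = predict_conc(p, dose, t, kind)
        ordered = predict_conc(p, dose, np.sort(t), kind)
        assert shuffled[np.argsort(t)] == pytest.approx(ordered, rel=1e-9)


class TestErrors:
    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            conc_onecomp_iv(PKParameters(cl=5, v=50), IV, [-1.0])

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            conc_onecomp_iv(PKParameters(cl=-5, v=50), IV, [1.0])

    def test_missing_ka_rejected(self):
        with pytest.raises(InvalidParameterError):
            conc_onecomp_abs(PKParameters(cl=5, v=50), ORAL, [1.0])

    def test_route_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            conc_onecomp_iv(PKParameters(cl=5, v=50), ORAL, [1.0])
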