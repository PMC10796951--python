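"""FracSeries algebra, the HATM/Picard recursions and h-curve diagnostics."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gamma

from fracliver.hatm import (
    HATMConfig,
    deformation_terms,
    h_curve,
    hatm_expand,
    hatm_solution,
    initial_derivatives,
    lambda_op,
    picard_coefficients,
    picard_solution,
    plateau_region,
    residual_diagnostic,
)
from fracliver.model import FractionalConfig, LiverParams, integer_solution
from fracliver.series import FracSeries, TruncationWarning


class TestLambdaOp:
    def test_constant_series(self, frac63):
        out = lambda_op(FracSeries(0.63, np.array([1.0])), frac63)
        # (1-v) local term plus v/Gamma(v+1) = 1/Gamma(v) on t^v
        assert out.coeffs[0] == pytest.approx(0.37, rel=1e-14)
        assert out.coeffs[1] == pytest.approx(1.0 / gamma(0.63), rel=1e-12)

    def test_integer_order_is_plain_integration(self):
        f1 = FractionalConfig(1.0)
        out = lambda_op(FracSeries(1.0, np.array([1.0])), f1)
        assert out.coeffs == pytest.approx([0.0, 1.0])  # 1 -> t
        out2 = lambda_op(out, f1)
        assert out2.coeffs == pytest.approx([0.0, 0.0, 0.5])  # t -> t^2/2

    @settings(deadline=None, max_examples=30)
    @given(
        a=st.floats(-2.0, 2.0),
        b=st.floats(-2.0, 2.0),
        c1=st.lists(st.floats(-5.0, 5.0), min_size=1, max_size=6),
        c2=st.lists(st.floats(-5.0, 5.0), min_size=1, max_size=6),
    )
    def test_linearity(self, a, b, c1, c2):
        f = FractionalConfig(0.63)
        s1 = FracSeries(0.63, np.array(c1))
        s2 = FracSeries(0.63, np.array(c2))
        lhs = lambda_op(a * s1 + b * s2, f)
        rhs = a * lambda_op(s1, f) + b * lambda_op(s2, f)
        np.testing.assert_allclose(lhs.coeffs, rhs.pad(len(lhs)).coeffs, atol=1e-10)


class TestSeriesEvaluate:
    def test_value_at_zero_is_leading_coefficient(self):
        s = FracSeries(0.63, np.array([3.0, 1.0, -2.0]))
        assert s.evaluate(0.0) == 3.0

    def test_truncation_warning(self):
        s = FracSeries(0.63, np.array([1.0, 1.0]))
        with pytest.warns(TruncationWarning):
            s.evaluate(10.0, check_truncation=True)


class TestHATMRecursion:
    def test_first_deformation_term_closed_form(self, params, frac63, blood_times):
        # R1 = alpha h H R0 (rho^(1-v)/M)(1 - v + t^v/Gamma(v)); W1 = -R1 for W0=0
        Rs, Ws = hatm_expand(params, frac63, HATMConfig(order=1))
        t = blood_times[1:]
        expected = (
            params.alpha * (-1.0) * params.R0 * (0.37 + t**0.63 / gamma(0.63))
        )
        np.testing.assert_allclose(Rs[1].evaluate(t), expected, rtol=1e-12)
        np.testing.assert_allclose(Ws[1].evaluate(t), -expected, rtol=1e-12)

    def test_picard_equals_hatm_at_minus_one(self, params, frac63):
        R, W = hatm_solution(params, frac63, HATMConfig(order=20))
        Rp, Wp = picard_solution(params, frac63, 20)
        n = max(len(R), len(Rp))
        np.testing.assert_allclose(R.pad(n).coeffs, Rp.pad(n).coeffs, atol=1e-10)
        np.testing.assert_allclose(W.pad(n).coeffs, Wp.pad(n).coeffs, atol=1e-10)

    def test_picard_zero_iterations_is_initial_state(self, params, frac63):
        R, W = picard_solution(params, frac63, 0)
        assert R.coeffs.tolist() == [params.R0]
        assert W.coeffs.tolist() == [params.W0]

    def test_integer_limit_matches_matrix_exponential(self, params):
        f1 = FractionalConfig(1.0)
        R, W = hatm_solution(params, f1, HATMConfig(order=30))
        times = np.linspace(0.5, 43.0, 30)
        tr = integer_solution(params, times)
        np.testing.assert_allclose(R.evaluate(times), tr.R, rtol=1e-6)
        np.testing.assert_allclose(W.evaluate(times), tr.W, rtol=1e-6)

    def test_integer_limit_maclaurin_coefficients(self, params):
        # term-by-term comparison with the matrix-exponential Taylor series
        f1 = FractionalConfig(1.0)
        R, W = hatm_solution(params, f1, HATMConfig(order=12))
        A = params.matrix
        # derivative recursion y^(k+1) = A y^(k) gives coefficients y^(k)/k!
        y = np.array([params.R0, params.W0])
        for k in range(9):
            assert R.coeffs[k] == pytest.approx(
                y[0] / math.factorial(k), rel=1e-10, abs=1e-12
            )
            assert W.coeffs[k] == pytest.approx(
                y[1] / math.factorial(k), rel=1e-10, abs=1e-12
            )
            y = A @ y

    def test_coefficient_decay(self, params, frac63):
        R, _ = picard_solution(params, frac63, 30)
        assert abs(R.coeffs[25]) < 1e-6 * abs(R.coeffs[5])

    def test_order_plateau_at_large_time(self, params, frac63):
        R25, _ = hatm_solution(params, frac63, HATMConfig(order=25))
        R40, _ = hatm_solution(params, frac63, HATMConfig(order=40))
        v25 = R25.evaluate(43.0)
        v40 = R40.evaluate(43.0)
        assert abs(v25 / v40 - 1.0) < 1e-8

    def test_fast_coefficient_path_matches_object_path(self, params, frac63):
        Rc, Wc = picard_coefficients(params, frac63, 15)
        R, W = picard_solution(params, frac63, 15)
        np.testing.assert_array_equal(Rc, R.coeffs)
        np.testing.assert_array_equal(Wc, W.coeffs)


class TestSymbolicIdentity:
    def test_order_two_partial_sums_match_printed_closed_forms(self):
        """Machine-verified equality with the published order-2 series.

        Exact rational/Gamma arithmetic in sympy: the order-<=2 recursion
        output must reproduce the closed forms R0 + hH(2+hH) R0 a L1 +
        (a+b) R0 a h^2 H^2 L2 and the sign-mirrored W sum with a+b+d,
        where L1 = (rho^(1-v)/M)(1-v+t^v/G(v)) and L2 its square kernel.
        """
        import sympy as sp

        a, b, d, R0, h, H, v, rho, M, t = sp.symbols(
            "alpha beta delta R_0 h H vartheta rho M t", positive=True
        )
        cfg = SimpleNamespace(vartheta=v, rho=rho, M=M)
        R0s = FracSeries(v, np.array([R0], dtype=object))
        W0s = FracSeries(v, np.array([0], dtype=object))
        Rs, Ws = deformation_terms(
            R0s,
            W0s,
            lambda R, W: (-a) * R + b * W,
            lambda R, W: a * R + (-(b + d)) * W,
            lambda s: lambda_op(s, cfg),
            h,
            H,
            2,
        )
        L1 = rho ** (1 - v) / M * (1 - v + t**v / sp.gamma(v))
        L2 = rho ** (2 - 2 * v) / M**2 * (
            (1 - v) ** 2
            + 2 * (1 - v) * t**v / sp.gamma(v)
            + v**2 * t ** (2 * v) / sp.gamma(2 * v + 1)
        )
        # first-order terms and their sign mirror
        assert sp.simplify(Rs[1].evaluate(t) - a * h * H * R0 * L1) == 0
        assert sp.simplify(Ws[1].evaluate(t) + a * h * H * R0 * L1) == 0
        # order-2 partial sums
        sumR = Rs[0].evaluate(t) + Rs[1].evaluate(t) + Rs[2].evaluate(t)
        sumW = Ws[0].evaluate(t) + Ws[1].evaluate(t) + Ws[2].evaluate(t)
        printedR = R0 + h * H * (2 + h * H) * R0 * a * L1 + (a + b) * R0 * a * h**2 * H**2 * L2
        printedW = -h * H * (2 + h * H) * R0 * a * L1 - (a + b + d) * R0 * a * h**2 * H**2 * L2
        assert sp.simplify(sumR - printedR) == 0
        assert sp.simplify(sumW - printedW) == 0


class TestInitialDerivatives:
    def test_clinical_value_at_h_minus_one(self, params):
        d = initial_derivatives(params, -1.0)
        assert d.R1 == pytest.approx(-13.684, rel=1e-12)

    @pytest.mark.parametrize("h", [-1.7, -1.0, -0.3])
    def test_structure(self, params, h):
        d = initial_derivatives(params, h)
        assert d.R3 == 0.0 and d.W3 == 0.0
        assert d.W1 == -d.R1
        assert d.R1 == pytest.approx((2 + h) * h * params.R0 * params.alpha)

    def test_matches_order_two_series_derivatives(self, params):
        # differentiate the order-2 HATM sum at integer order symbolically in t
        import sympy as sp

        h = -0.8
        f1 = FractionalConfig(1.0)
        Rs, Ws = hatm_expand(params, f1, HATMConfig(h=h, H=1.0, order=2))
        t = sp.Symbol("t")
        sumR = sum(
            float(c) * t**k for s in Rs for k, c in enumerate(s.pad(4).coeffs)
        )
        d = initial_derivatives(params, h)
        assert float(sp.diff(sumR, t, 1).subs(t, 0)) == pytest.approx(d.R1, rel=1e-12)
        assert float(sp.diff(sumR, t, 2).subs(t, 0)) == pytest.approx(d.R2, rel=1e-12)
        assert float(sp.diff(sumR, t, 3).subs(t, 0)) == pytest.approx(d.R3, abs=1e-12)


class TestHCurve:
    def test_roots_at_factor_zeros(self, params):
        tab = h_curve(params, np.array([-2.0, -1.0]))
        assert tab["R1"].iloc[0] == pytest.approx(0.0, abs=1e-14)  # h = -2 root

    def test_third_derivative_row_identically_zero(self, params):
        tab = h_curve(params, np.arange(-2.0, -0.005, 0.01))
        assert np.allclose(tab["R3"], 0.0) and np.allclose(tab["W3"], 0.0)

    def test_plateau_contains_published_interval(self, params):
        tab = h_curve(params, np.arange(-2.0, -0.005, 0.01))
        pl = plateau_region(tab, slope_tol=0.05)
        assert not pl.empty
        lo, hi = pl.interval
        assert lo <= -1.5 and hi >= -0.5

    def test_grid_with_zero_rejected(self, params):
        with pytest.raises(ValueError):
            h_curve(params, np.array([-1.0, 0.0]))

    def test_empty_plateau_is_result_not_error(self, params):
        # a 2-point grid across the sign change cannot be flat
        tab = h_curve(params, np.array([-1.99, -0.01]))
        pl = plateau_region(tab, slope_tol=1e-6)
        assert pl.empty and pl.interval is None


class TestResidualDiagnostic:
    def test_converged_series_residual_small(self, params, frac63):
        pair = picard_solution(params, frac63, 30)
        res = residual_diagnostic(pair, params, frac63, np.linspace(0.5, 43.0, 40))
        assert res < 1e-7 * params.R0

    def test_monotone_improvement_with_order(self, params, frac63):
        r1 = residual_diagnostic(
            picard_solution(params, frac63, 1), params, frac63, [43.0]
        )
        r10 = residual_diagnostic(
            picard_solution(params, frac63, 10), params, frac63, [43.0]
        )
        assert r10 < r1

    def test_zero_rate_model_residual_exact_zero(self, frac63):
        p = LiverParams(0.0, 0.0, 0.0, 100.0, 0.0)
        pair = picard_solution(p, frac63, 5)
        assert residual_diagnostic(pair, p, frac63, [1.0, 10.0]) == 0.0


class TestHATMConfigValidation:
    def test_rejects_zero_h_or_H(self):
        with pytest.raises(ValueError):
            HATMConfig(h=0.0)
        with pytest.raises(ValueError):
            HATMConfig(H=0.0)
        with pytest.raises(ValueError):
            HATMConfig(order=0)
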