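"""Integer-order closed form, Lipschitz constants, existence horizons."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fracliver.model import (
    ExistenceReport,
    FractionalConfig,
    LiverParams,
    Trajectory,
    existence_check,
    integer_solution,
    lipschitz_constants,
    vector_field,
)


class TestVectorField:
    def test_clinical_initial_slope(self, params):
        q1, q2 = vector_field(params, (250.0, 0.0))
        assert q1 == pytest.approx(-13.684, rel=1e-12)
        assert q2 == pytest.approx(13.684, rel=1e-12)

    def test_origin_is_fixed_point(self, params):
        assert vector_field(params, (0.0, 0.0)) == (0.0, 0.0)

    def test_closed_transfer_conserves_mass(self):
        p = LiverParams(0.1, 0.0, 0.0, 100.0, 5.0)
        q1, q2 = vector_field(p, (80.0, 25.0))
        assert q1 + q2 == pytest.approx(0.0, abs=1e-14)


class TestIntegerSolution:
    def test_initial_conditions(self, params):
        tr = integer_solution(params, [0.0, 1.0])
        assert tr.R[0] == params.R0 and tr.W[0] == params.W0

    def test_matches_adaptive_integrator(self, params):
        times = np.linspace(0.0, 43.0, 44)
        tr = integer_solution(params, times)
        sol = solve_ivp(
            lambda t, y: vector_field(params, y),
            (0.0, 43.0),
            [params.R0, params.W0],
            t_eval=times,
            rtol=1e-12,
            atol=1e-12,
            method="DOP853",
        )
        assert np.allclose(tr.R, sol.y[0], rtol=1e-9)
        assert np.allclose(tr.W, sol.y[1], rtol=1e-9)

    def test_conservation_without_elimination(self):
        p = LiverParams(0.05, 0.02, 0.0, 250.0, 10.0)
        tr = integer_solution(p, np.linspace(0.0, 100.0, 50))
        assert np.allclose(tr.R + tr.W, p.R0 + p.W0, rtol=1e-12)

    def test_repeated_eigenvalue_branch(self):
        # alpha = beta + delta and beta = 0 makes the matrix defective-free
        # but equal-eigenvalue; compare against the adaptive integrator
        p = LiverParams(0.1, 0.0, 0.1, 50.0, 0.0)
        times = np.linspace(0.0, 20.0, 21)
        tr = integer_solution(p, times)
        sol = solve_ivp(
            lambda t, y: vector_field(p, y),
            (0.0, 20.0),
            [p.R0, p.W0],
            t_eval=times,
            rtol=1e-12,
            atol=1e-12,
            method="DOP853",
        )
        assert np.allclose(tr.R, sol.y[0], rtol=1e-8, atol=1e-10)

    def test_mass_decay_rate_is_liver_elimination(self, params):
        # d/dt (R+W) = -delta W, checked by finite differences
        times = np.linspace(0.0, 43.0, 2000)
        tr = integer_solution(params, times)
        total = tr.R + tr.W
        dt = times[1] - times[0]
        mid_W = 0.5 * (tr.W[1:] + tr.W[:-1])
        assert np.allclose(np.diff(total) / dt, -params.delta * mid_W, atol=1e-5)
        assert np.all(np.diff(total) <= 0)

    def test_stays_nonnegative(self, params):
        tr = integer_solution(params, np.linspace(0.0, 200.0, 400))
        assert np.all(tr.R >= 0) and np.all(tr.W >= 0)


class TestExistence:
    def test_lipschitz_constants(self, params):
        l1, l2 = lipschitz_constants(params)
        assert l1 == params.alpha
        assert l2 == pytest.approx(0.0246610, abs=1e-7)
        assert lipschitz_constants(LiverParams(0.0, 0.0, 0.0, 1.0)) == (0.0, 0.0)

    def test_contraction_flag(self, params):
        rep = existence_check(params, FractionalConfig(0.63), 1.0)
        assert rep.contraction_flag  # 0 < alpha <= 1

    def test_clinical_horizon(self, params, frac63):
        rep = existence_check(params, frac63, 0.0)
        expected = (1.0 - 0.37 * params.alpha) / (0.63 * params.alpha)
        assert rep.horizons[0] == pytest.approx(expected, rel=1e-12)
        assert rep.horizons[0] == pytest.approx(28.41, abs=0.01)

    def test_condition_true_at_zero_and_infinite_for_zero_rate(self, frac63):
        p = LiverParams(0.0, 0.0, 0.0, 1.0)
        rep = existence_check(p, frac63, 0.0)
        assert rep.satisfied == (True, True)
        assert rep.horizons == (math.inf, math.inf)

    def test_horizon_decreases_with_rate_and_prefactor(self):
        horizons = []
        for lam in (0.01, 0.05, 0.1):
            p = LiverParams(lam, 0.0, 0.0, 1.0)
            horizons.append(existence_check(p, FractionalConfig(0.63), 0.0).horizons[0])
        assert horizons[0] > horizons[1] > horizons[2]
        p = LiverParams(0.05, 0.0, 0.0, 1.0)
        hs = [
            existence_check(p, FractionalConfig(0.63, rho=r), 0.0).horizons[0]
            for r in (0.5, 1.0, 2.0)
        ]  # rho^(1-v) increases with rho
        assert hs[0] > hs[1] > hs[2]

    def test_integer_order_rejected(self, params):
        with pytest.raises(ValueError):
            existence_check(params, FractionalConfig(1.0), 1.0)


class TestTypes:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            LiverParams(-0.1, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            LiverParams(0.1, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            LiverParams(0.1, 0.0, 0.0, 1.0, -1.0)

    def test_fractional_config(self):
        with pytest.raises(ValueError):
            FractionalConfig(0.0)
        with pytest.raises(ValueError):
            FractionalConfig(1.2)
        f = FractionalConfig(0.63)
        assert f.mu == pytest.approx(0.63 / 0.37)
        assert f.M == 1.0
        g = FractionalConfig(0.63, normalization="ab_standard")
        assert g.M == pytest.approx(1 - 0.63 + 0.63 / math.gamma(0.63))
        with pytest.raises(ValueError):
            _ = FractionalConfig(1.0).mu

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            Trajectory([0.0, 0.0], [1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            Trajectory([0.0, 1.0], [1.0], [0.0, 0.0])
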