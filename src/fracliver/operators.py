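"""Numerical fractional operators: RL integral, MABC derivative, MAB integral.

These operators realize, as direct quadrature, the calculus underlying the
fractional liver model:

* the Riemann-Liouville (RL) fractional integral of order ``nu``,
* the modified Atangana-Baleanu derivative in the Caputo sense (MABC) of
  order ``vartheta`` in (0, 1), whose kernel is the two-parameter
  Mittag-Leffler function and which annihilates constants,
* the associated MAB fractional integral (the left inverse of the MABC
  derivative up to f(0)),
* the Laplace-domain image of the MABC derivative.

They are deliberately independent of the series and Laplace solvers so they
can serve as cross-checking oracles for those layers.

Quadrature notes
----------------
``rl_integral`` uses the classical product-trapezoid rule: the power weight
(t-xi)^(nu-1) is integrated exactly on each panel against a piecewise-linear
interpolant of f, giving O(h^2) convergence for smooth f with no special
treatment of the endpoint singularity.

``mabc_derivative`` needs far higher accuracy on its kernel integral (the
defining property "derivative of a constant is zero" is a near-perfect
cancellation).  The substitution w = (t-xi)^vartheta removes the singularity
*exactly* -- the integrand becomes (1/vartheta) E_{v,v}(-mu w) f(t - w^(1/v))
on [0, t^vartheta] -- and composite Simpson on the transformed axis then
converges at O(h^4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import gamma as _gamma

from .special import _ml_neg_array, ml_one

__all__ = [
    "QuadratureConfig",
    "rl_integral",
    "mabc_derivative",
    "mab_integral",
    "laplace_of_mabc",
]


@dataclass(frozen=True)
class QuadratureConfig:
    """Discretization controls for the operator quadratures."""

    n_panels: int = 2048
    scheme: str = "product_trapezoid"
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_panels < 8:
            raise ValueError("n_panels must be >= 8")
        if self.scheme not in {"product_trapezoid"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not (self.tol > 0):
            raise ValueError("tol must be positive")


_DEFAULT_Q = QuadratureConfig()


def rl_integral(
    f: Callable[[np.ndarray], np.ndarray],
    nu: float,
    t: float,
    q: QuadratureConfig = _DEFAULT_Q,
) -> float:
    """Riemann-Liouville fractional integral (1/Gamma(nu)) int_0^t (t-xi)^(nu-1) f(xi) dxi.

    Product-trapezoid rule: exact integration of the power weight against a
    piecewise-linear interpolant of ``f`` on a uniform grid.
    """
    if not (0.0 < nu <= 1.0):
        raise ValueError(f"nu must lie in (0, 1], got {nu}")
    if not (t > 0):
        raise ValueError(f"t must be positive, got {t}")
    n = q.n_panels
    h = t / n
    xi = np.linspace(0.0, t, n + 1)
    fx = np.asarray(f(xi), dtype=float)
    # classical piecewise-linear product-integration weights (Diethelm form):
    # I = h^nu / Gamma(nu+2) * sum_j a_j f(xi_j)
    j = np.arange(1, n)
    a = np.empty(n + 1)
    a[0] = (n - 1) ** (nu + 1) - (n - nu - 1) * n**nu
    a[1:n] = (n - j + 1) ** (nu + 1) - 2 * (n - j) ** (nu + 1) + (n - j - 1) ** (nu + 1)
    a[n] = 1.0
    return float(h**nu / _gamma(nu + 2) * np.dot(a, fx))


def _mabc_kernel_integral(
    f: Callable[[np.ndarray], np.ndarray],
    vartheta: float,
    t: float,
    mu: float,
    n_panels: int,
) -> float:
    """mu * int_0^t (t-xi)^(v-1) E_{v,v}(-mu (t-xi)^v) f(xi) dxi.

    Computed after the exact substitution w = (t-xi)^v, which turns the
    singular kernel into the constant 1/v:

        = (mu/v) * int_0^{t^v} E_{v,v}(-mu w) f(t - w^(1/v)) dw

    and integrated with composite Simpson (n_panels even).
    """
    n = n_panels + (n_panels % 2)  # Simpson needs an even panel count
    W = t**vartheta

    def simpson_piece(a: float, b: float, m: int) -> float:
        w = np.linspace(a, b, m + 1)
        x = t - w ** (1.0 / vartheta)
        x[0] = t if a == 0.0 else x[0]
        if b == W:
            x[-1] = 0.0
        g = _ml_neg_array(vartheta, vartheta, mu * w) * np.asarray(f(x), dtype=float)
        weights = np.ones(m + 1)
        weights[1:-1:2] = 4.0
        weights[2:-1:2] = 2.0
        return (b - a) / m / 3.0 * float(np.dot(weights, g))

    # the ML kernel decays on the scale 1/mu; resolve that boundary layer
    # separately when the integration range is much longer than it
    w_split = 8.0 / mu
    if W > 2.0 * w_split:
        simpson = simpson_piece(0.0, w_split, n) + simpson_piece(w_split, W, n)
    else:
        simpson = simpson_piece(0.0, W, n)
    return mu / vartheta * simpson


def mabc_derivative(
    f: Callable[[np.ndarray], np.ndarray],
    vartheta: float,
    t: float,
    M: float = 1.0,
    q: QuadratureConfig = _DEFAULT_Q,
) -> float:
    """Modified Atangana-Baleanu-Caputo derivative of ``f`` at ``t``.

    (M/(1-v)) [ f(t) - E_v(-mu t^v) f(0) - mu int_0^t (t-xi)^(v-1)
                E_{v,v}(-mu (t-xi)^v) f(xi) dxi ],   mu = v/(1-v).

    Annihilates constants by construction (the kernel integral of 1 equals
    1 - E_v(-mu t^v) exactly).
    """
    if not (0.0 < vartheta < 1.0):
        raise ValueError(f"vartheta must lie strictly in (0, 1), got {vartheta}")
    if not (t > 0):
        raise ValueError(f"t must be positive, got {t}")
    mu = vartheta / (1.0 - vartheta)
    f0 = float(np.asarray(f(np.array([0.0])))[0])
    ft = float(np.asarray(f(np.array([t])))[0])
    ml0 = ml_one(vartheta, -mu * t**vartheta)
    ki = _mabc_kernel_integral(f, vartheta, t, mu, q.n_panels)
    return M / (1.0 - vartheta) * (ft - ml0 * f0 - ki)


def mab_integral(
    f: Callable[[np.ndarray], np.ndarray],
    vartheta: float,
    t: float,
    M: float = 1.0,
    q: QuadratureConfig = _DEFAULT_Q,
) -> float:
    """MAB fractional integral, the inversion partner of the MABC derivative.

    ((1-v)/M) [ f(t) + mu RL^v[f](t) - f(0) - mu f(0) t^v / Gamma(v+1) ].
    """
    if not (0.0 < vartheta < 1.0):
        raise ValueError(f"vartheta must lie strictly in (0, 1), got {vartheta}")
    if not (t > 0):
        raise ValueError(f"t must be positive, got {t}")
    mu = vartheta / (1.0 - vartheta)
    f0 = float(np.asarray(f(np.array([0.0])))[0])
    ft = float(np.asarray(f(np.array([t])))[0])
    rl = rl_integral(f, vartheta, t, q)
    return (1.0 - vartheta) / M * (
        ft + mu * rl - f0 - mu * f0 * t**vartheta / _gamma(vartheta + 1.0)
    )


def laplace_of_mabc(
    f0: float,
    F_hat: Callable[[complex], complex],
    vartheta: float,
    s: complex,
    M: float = 1.0,
) -> complex:
    """Laplace image of the MABC derivative, principal branch of s^v.

    (M/(1-v)) (s^v F(s) - s^(v-1) f0) / (s^v + mu),  Re(s) > 0.
    """
    if not (0.0 < vartheta < 1.0):
        raise ValueError(f"vartheta must lie strictly in (0, 1), got {vartheta}")
    s = complex(s)
    if not (s.real > 0):
        raise ValueError(f"Re(s) must be positive, got {s}")
    mu = vartheta / (1.0 - vartheta)
    sv = s**vartheta
    val = M / (1.0 - vartheta) * (sv * F_hat(s) - sv / s * f0) / (sv + mu)
    return val
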