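"""Homotopy-analysis-transform (HATM) and Picard solution of the fractional model.

The Laplace transform turns the MABC liver system into the fixed-point form

    L[R] = R(0)/P + (rho^(1-v)/M) (1 - v + v/P^v) L[-alpha R + beta W]

(and the mirrored W equation).  Back in the time domain the bracketed
multiplier acts on generalized power series as the linear operator

    Lambda: t^(kv) -> (rho^(1-v)/M) [ (1-v) t^(kv)
                                      + v Gamma(kv+1)/Gamma(kv+v+1) t^((k+1)v) ],

so both the Picard iteration and the HATM deformation recursion stay inside
the FracSeries space and can be carried in closed form.

HATM embeds the problem in a homotopy with convergence-control parameter h
and constant auxiliary function H; the eta-th deformation term obeys

    R_eta = psi_eta R_{eta-1} + h H [ R_{eta-1} - (1-psi_eta) R(0)
                                      - Lambda(-alpha R_{eta-1} + beta W_{eta-1}) ]

with psi_eta = 0 for eta <= 1 and 1 otherwise (W mirrored with kernel
alpha R - (beta+delta) W).  At h = -1, H = 1 the partial sums collapse
telescopically onto the Picard iterates, which is also the series' fixed
point; any other h in the flat region of the h-curves converges to the same
limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import FractionalConfig, LiverParams
from .series import FracSeries

__all__ = [
    "HATMConfig",
    "InitialDerivatives",
    "PlateauResult",
    "lambda_op",
    "hatm_expand",
    "hatm_solution",
    "picard_solution",
    "initial_derivatives",
    "h_curve",
    "plateau_region",
    "residual_diagnostic",
]


@dataclass(frozen=True)
class HATMConfig:
    """Convergence-control parameter h, auxiliary constant H, truncation order."""

    h: float = -1.0
    H: float = 1.0
    order: int = 25

    def __post_init__(self) -> None:
        if self.h == 0:
            raise ValueError("h must be nonzero")
        if self.H == 0:
            raise ValueError("H must be nonzero")
        if self.order < 1:
            raise ValueError("order must be >= 1")


_GAMMA_RATIO_CACHE: dict[tuple[float, int], np.ndarray] = {}


def _gamma_ratio(n: int, v: float) -> np.ndarray:
    """Gamma(kv+1)/Gamma(kv+v+1) for k = 0..n-1, without overflow (cached)."""
    key = (v, n)
    out = _GAMMA_RATIO_CACHE.get(key)
    if out is None:
        kv = np.arange(n) * v
        out = np.exp(gammaln(kv + 1.0) - gammaln(kv + v + 1.0))
        if len(_GAMMA_RATIO_CACHE) > 512:
            _GAMMA_RATIO_CACHE.clear()
        _GAMMA_RATIO_CACHE[key] = out
    return out


def lambda_op(s: FracSeries, f: Any) -> FracSeries:
    """Apply the Laplace-domain solution operator Lambda to a series.

    ``f`` needs attributes ``vartheta``, ``rho`` and ``M`` (a
    :class:`FractionalConfig` in production, or a namespace of sympy symbols
    for symbolic verification).
    """
    v = f.vartheta
    symbolic = s.coeffs.dtype == object or not isinstance(v, (int, float))
    pref = f.rho ** (1 - v) / f.M
    n = len(s.coeffs)
    if symbolic:
        import sympy as sp

        out = np.zeros(n + 1, dtype=object)
        for k, c in enumerate(s.coeffs):
            out[k] += pref * (1 - v) * c
            out[k + 1] += pref * v * sp.gamma(k * v + 1) / sp.gamma(k * v + v + 1) * c
        return FracSeries(s.vartheta, out)
    out = np.zeros(n + 1)
    out[:-1] += pref * (1.0 - v) * s.coeffs
    out[1:] += pref * v * _gamma_ratio(n, v) * s.coeffs
    return FracSeries(s.vartheta, out)


def _kernels(p: LiverParams):
    """Model kernels acting on series pairs."""

    def kR(R: FracSeries, W: FracSeries) -> FracSeries:
        return -p.alpha * R + p.beta * W

    def kW(R: FracSeries, W: FracSeries) -> FracSeries:
        return p.alpha * R - (p.beta + p.delta) * W

    return kR, kW


def deformation_terms(
    R0_series: FracSeries,
    W0_series: FracSeries,
    kernel_R,
    kernel_W,
    lam,
    h: Any,
    H: Any,
    order: int,
) -> tuple[list[FracSeries], list[FracSeries]]:
    """Generic eta-th order deformation recursion (numeric or symbolic)."""
    Rs = [R0_series]
    Ws = [W0_series]
    for eta in range(1, order + 1):
        psi = 0 if eta <= 1 else 1
        Rp, Wp = Rs[-1], Ws[-1]
        TR = Rp - (1 - psi) * R0_series - lam(kernel_R(Rp, Wp))
        TW = Wp - (1 - psi) * W0_series - lam(kernel_W(Rp, Wp))
        Rs.append(psi * Rp + (h * H) * TR)
        Ws.append(psi * Wp + (h * H) * TW)
    return Rs, Ws


def hatm_expand(
    p: LiverParams, f: FractionalConfig, c: HATMConfig = HATMConfig()
) -> tuple[list[FracSeries], list[FracSeries]]:
    """Deformation terms {R_eta}, {W_eta}, eta = 0..order."""
    R0s = FracSeries(f.vartheta, np.array([p.R0]))
    W0s = FracSeries(f.vartheta, np.array([p.W0]))
    kR, kW = _kernels(p)
    return deformation_terms(R0s, W0s, kR, kW, lambda s: lambda_op(s, f), c.h, c.H, c.order)


def hatm_solution(
    p: LiverParams, f: FractionalConfig, c: HATMConfig = HATMConfig()
) -> tuple[FracSeries, FracSeries]:
    """Summed HATM series (R, W); evaluate with ``FracSeries.evaluate``."""
    Rs, Ws = hatm_expand(p, f, c)
    R = Rs[0]
    W = Ws[0]
    for r, w in zip(Rs[1:], Ws[1:]):
        R = R + r
        W = W + w
    return R, W


def picard_coefficients(
    p: LiverParams, f: FractionalConfig, n_iter: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Raw coefficient arrays of the Picard iterates (fast path, no objects).

    Same recursion as :func:`picard_solution`; used directly by the fitting
    loop where series objects would dominate the runtime.
    """
    v = f.vartheta
    pref = f.prefactor
    R = np.array([p.R0])
    W = np.array([p.W0])
    a, bd, b = p.alpha, p.beta + p.delta, p.beta
    for _ in range(n_iter):
        n = len(R)
        ratio = _gamma_ratio(n, v)
        kR = -a * R + b * W
        kW = a * R - bd * W
        Rn = np.zeros(n + 1)
        Wn = np.zeros(n + 1)
        Rn[:-1] = pref * (1.0 - v) * kR
        Rn[1:] += pref * v * ratio * kR
        Wn[:-1] = pref * (1.0 - v) * kW
        Wn[1:] += pref * v * ratio * kW
        Rn[0] += p.R0
        Wn[0] += p.W0
        R, W = Rn, Wn
    return R, W


def picard_solution(
    p: LiverParams, f: FractionalConfig, n_iter: int = 25
) -> tuple[FracSeries, FracSeries]:
    """Picard iterates of the Laplace fixed-point form (equals HATM at h=-1, H=1)."""
    if not (0.0 < f.vartheta <= 1.0):
        raise ValueError("vartheta must lie in (0, 1]")
    R, W = picard_coefficients(p, f, n_iter)
    return FracSeries(f.vartheta, R), FracSeries(f.vartheta, W)


class InitialDerivatives(NamedTuple):
    """t=0 derivatives of the order-2 HATM partial sum (H = 1, vartheta = 1)."""

    R1: float
    R2: float
    R3: float
    W1: float
    W2: float
    W3: float


def initial_derivatives(p: LiverParams, h: float) -> InitialDerivatives:
    """Closed-form initial derivatives used for the h-curve diagnostics.

    Derivatives at t = 0 of the order-2 partial sum at integer order with
    H = 1: R'(0) = (2+h) h R0 alpha, R''(0) = (alpha+beta) h^2 R0 alpha,
    R'''(0) = 0, and the W quantities sign-mirrored with alpha+beta+delta.
    """
    a = p.alpha
    base = p.R0 * a
    return InitialDerivatives(
        R1=(2.0 + h) * h * base,
        R2=(a + p.beta) * h * h * base,
        R3=0.0,
        W1=-(2.0 + h) * h * base,
        W2=-(a + p.beta + p.delta) * h * h * base,
        W3=0.0,
    )


def h_curve(p: LiverParams, h_grid: Sequence[float]) -> pd.DataFrame:
    """Tabulate the six initial derivatives against h."""
    h_grid = np.asarray(h_grid, dtype=float)
    if np.any(h_grid == 0):
        raise ValueError("h_grid must exclude 0")
    rows = [initial_derivatives(p, h) for h in h_grid]
    df = pd.DataFrame(rows, columns=InitialDerivatives._fields)
    df.insert(0, "h", h_grid)
    return df


@dataclass(frozen=True)
class PlateauResult:
    """Maximal contiguous h-interval on which all nonzero curves are flat."""

    interval: tuple[float, float] | None
    message: str = ""

    @property
    def empty(self) -> bool:
        return self.interval is None


def plateau_region(table: pd.DataFrame, slope_tol: float = 0.05) -> PlateauResult:
    """Detect the flat region of the h-curves.

    A grid step is "flat" for one curve when the change across the step is
    at most ``slope_tol`` times the local magnitude of the curve; curves
    that are identically zero (e.g. the third derivatives) carry no
    information and are skipped.  The result is the longest run of steps
    flat for *every* informative curve.
    """
    h = table["h"].to_numpy()
    curves = [c for c in table.columns if c != "h"]
    ok = np.ones(len(h) - 1, dtype=bool)
    informative = 0
    for c in curves:
        q = table[c].to_numpy()
        if np.allclose(q, 0.0):
            continue
        informative += 1
        mag = np.maximum(np.abs(q[:-1]), np.abs(q[1:]))
        ok &= np.abs(np.diff(q)) <= slope_tol * mag
    if informative == 0 or not ok.any():
        return PlateauResult(None, "no flat region found on the supplied grid")
    # longest contiguous run of flat steps
    best_len = cur_len = 0
    best_end = 0
    for i, flag in enumerate(ok):
        cur_len = cur_len + 1 if flag else 0
        if cur_len > best_len:
            best_len, best_end = cur_len, i
    lo = h[best_end - best_len + 1]
    hi = h[best_end + 1]
    return PlateauResult((float(lo), float(hi)))


def residual_diagnostic(
    series_pair: tuple[FracSeries, FracSeries],
    p: LiverParams,
    f: FractionalConfig,
    t_grid: Sequence[float],
) -> float:
    """Max absolute residual of the Laplace fixed-point form on ``t_grid``.

    Evaluates R - R(0) - Lambda(-alpha R + beta W) and the mirrored W
    equation; for a converged series both vanish up to the truncation tail.
    """
    R, W = series_pair
    kR, kW = _kernels(p)
    resR = R - FracSeries(f.vartheta, np.array([p.R0])) - lambda_op(kR(R, W), f)
    resW = W - FracSeries(f.vartheta, np.array([p.W0])) - lambda_op(kW(R, W), f)
    t_grid = np.asarray(t_grid, dtype=float)
    vals = np.concatenate([np.atleast_1d(resR.evaluate(t_grid)), np.atleast_1d(resW.evaluate(t_grid))])
    return float(np.max(np.abs(vals)))
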