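"""Generalized power series sum_k c_k t^(k*vartheta).

The Laplace-domain solution operator of the fractional liver model maps
t^(k v) to a combination of t^(k v) and t^((k+1) v), so the space of these
series is closed under every step of the HATM / Picard recursions.  A
``FracSeries`` is the closed-form carrier of those iterates.

Coefficients may be floats (production path) or sympy expressions (used to
machine-verify the low-order closed forms); arithmetic is coefficientwise
and dispatches on the coefficient type.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = ["FracSeries", "TruncationWarning"]


class TruncationWarning(UserWarning):
    """Evaluation used a series whose last retained term is not negligible."""


def _is_symbolic(coeffs: np.ndarray) -> bool:
    return coeffs.dtype == object


@dataclass(frozen=True)
class FracSeries:
    """A truncated series sum_{k=0}^{K} coeffs[k] * t^(k * vartheta)."""

    vartheta: Any  # float in production; sympy expression in symbolic checks
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs)
        if c.dtype != object:
            c = np.asarray(c, dtype=float)
            if not np.all(np.isfinite(c)):
                raise ValueError("series coefficients must be finite")
        object.__setattr__(self, "coeffs", c)

    def __len__(self) -> int:
        return len(self.coeffs)

    def pad(self, n: int) -> "FracSeries":
        if n <= len(self):
            return self
        zero = 0 if _is_symbolic(self.coeffs) else 0.0
        c = np.concatenate([self.coeffs, np.full(n - len(self), zero, dtype=self.coeffs.dtype)])
        return FracSeries(self.vartheta, c)

    def _binop(self, other: "FracSeries", sign: float) -> "FracSeries":
        if not isinstance(other, FracSeries):
            return NotImplemented
        n = max(len(self), len(other))
        a = self.pad(n).coeffs
        b = other.pad(n).coeffs
        return FracSeries(self.vartheta, a + sign * b)

    def __add__(self, other: "FracSeries") -> "FracSeries":
        return self._binop(other, 1)

    def __sub__(self, other: "FracSeries") -> "FracSeries":
        return self._binop(other, -1)

    def __mul__(self, scalar: Any) -> "FracSeries":
        return FracSeries(self.vartheta, self.coeffs * scalar)

    __rmul__ = __mul__

    def __neg__(self) -> "FracSeries":
        return FracSeries(self.vartheta, -self.coeffs)

    def evaluate(self, t, check_truncation: bool = False):
        """Evaluate the series at scalar or array ``t`` (compensated sum).

        With ``check_truncation`` a :class:`TruncationWarning` is emitted when
        the last retained term exceeds 1e-8 of the sum in magnitude anywhere.
        """
        if _is_symbolic(self.coeffs):
            tt = t
            return sum(c * tt ** (k * self.vartheta) for k, c in enumerate(self.coeffs))
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        k = np.arange(len(self.coeffs))
        with np.errstate(divide="ignore"):
            # t=0: 0**0 = 1 handled explicitly
            powers = np.where(
                t_arr[:, None] == 0.0,
                np.where(k[None, :] == 0, 1.0, 0.0),
                np.exp(k[None, :] * self.vartheta * np.log(np.maximum(t_arr[:, None], 1e-300))),
            )
        terms = powers * self.coeffs[None, :]
        vals = np.array([math.fsum(row) for row in terms])
        if check_truncation and len(self.coeffs) > 1:
            last = np.abs(terms[:, -1])
            if np.any(last > 1e-8 * np.maximum(np.abs(vals), 1e-300)):
                warnings.warn(
                    "last retained series term exceeds 1e-8 of the sum; "
                    "truncation order may be insufficient at the largest t",
                    TruncationWarning,
                    stacklevel=2,
                )
        return vals if np.ndim(t) else float(vals[0])
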