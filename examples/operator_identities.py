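"""Check the defining identities of the MABC operator numerically.

Three facts make the MABC derivative usable for initial-value problems:
it annihilates constants, its paired MAB integral undoes it up to f(0),
and its Laplace image has the closed rational-in-s^v form.  Each is
verified here by direct quadrature, independently of the model solvers.
"""

import numpy as np

from fracliver import QuadratureConfig, laplace_of_mabc, mab_integral, mabc_derivative

vartheta = 0.63

r = mabc_derivative(lambda x: 7.0 * np.ones_like(x), vartheta, t=43.0)
print(f"MABC[7](t=43) = {r:.3e}   (a fractional derivative of a constant: ~0)")

q = QuadratureConfig(n_panels=512)
g = lambda x: x**2
dg = lambda x: np.array(
    [mabc_derivative(g, vartheta, float(t), q=q) if t > 0 else 0.0 for t in np.atleast_1d(x)]
)
val = mab_integral(dg, vartheta, t=5.0)
print(f"MAB[MABC[x^2]](5) = {val:.6f}   (recovers g(5) - g(0) = 25)")

s = 2.0
image = laplace_of_mabc(0.0, lambda ss: 1.0 / ss**2, vartheta, s).real
xg, wg = np.polynomial.laguerre.laggauss(60)
numeric = float(np.dot(wg, [mabc_derivative(lambda x: x, vartheta, float(t / s), q=q) for t in xg]) / s)
print(f"Laplace image at s=2: closed form {image:.8f}, quadrature {numeric:.8f}")
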