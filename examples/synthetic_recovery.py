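"""Generate a noisy synthetic BSP test and recover the rates that made it.

Simulates one BSP test at fractional order 0.63 with 5% multiplicative
measurement noise on both channels, then fits (alpha, beta, delta) with
the order fixed.  alpha (the blood-to-liver transfer) is well identified;
beta and delta barely shape the slow fractional curves, so their estimates
scatter widely -- exactly what the Fisher information predicts at these
study conditions.
"""

import numpy as np

from fracliver import FractionalConfig, NoiseModel, fit, generate, table1_params

p = table1_params()
f = FractionalConfig(0.63)
times = np.array([0.0, 3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0])

data = generate(
    p, f, times,
    noise=NoiseModel("multiplicative_lognormal", scale=0.05, seed=42),
    observe_liver=True,
)
print("noisy blood channel:", np.round(data.blood, 1))

result = fit(data, free=("alpha", "beta", "delta"), vartheta=0.63, n_starts=4)
print(f"\n{'rate':>6} {'truth':>10} {'recovered':>10} {'rel err':>8}")
for name in ("alpha", "beta", "delta"):
    truth, est = getattr(p, name), getattr(result.params, name)
    print(f"{name:>6} {truth:10.6f} {est:10.6f} {abs(est/truth-1):8.1%}")
print("\nalpha lands within ~10% of truth on a typical replicate (median ~6%")
print("across seeds); beta/delta are weakly identified by design of the")
print("test -- see docs/methods.md for the Fisher-information analysis.")
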