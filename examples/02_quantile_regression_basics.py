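"""Check-loss quantile regression on a tiny dataset, step by step.

Fits conditional quantiles of a heteroscedastic response and shows the
analytic fact the scan relies on: when a covariate scales the noise
(y = 1 + (1 + 0.5 x) z), the slope of the tau-quantile line is
0.5 * z_tau — negative in the lower tail, zero at the median, positive
in the upper tail — while the mean slope is zero.
"""

import numpy as np
from scipy import stats

from qrgwas import QRDesign, check_loss, fit_quantile, pseudo_r1

rng = np.random.default_rng(0)
n = 4000
x = rng.integers(0, 3, n).astype(float)
y = 1.0 + (1.0 + 0.5 * x) * rng.normal(size=n)

print("check function: rho_0.1(+2) =", check_loss(2.0, 0.1),
      " rho_0.1(-2) =", check_loss(-2.0, 0.1))

X = np.column_stack([np.ones(n), x])
print(f"\n{'tau':>5} {'slope':>8} {'analytic':>9} {'R1 vs null (%)':>14}")
for tau in (0.1, 0.25, 0.5, 0.75, 0.9):
    fit = fit_quantile(QRDesign(X, y, tau))
    null = fit_quantile(QRDesign(np.ones((n, 1)), y, tau))
    r1 = 100 * pseudo_r1(fit.objective, null.objective)
    print(f"{tau:5.2f} {fit.beta[1]:8.3f} {0.5 * stats.norm.ppf(tau):9.3f} {r1:14.2f}")
print("\nthe slope flips sign across the distribution: that signature is what",
      "\nthe quantile scan detects and a single mean regression cannot")
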