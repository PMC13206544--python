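"""Fit one seed lot's viability time course and read off sigma, Ki, p50.

Simulates a lot aged at 45 degC / 60% RH with true Ki = 2 probits
(~97.7% initial viability) and true sigma = 20 days, fits the
quasi-binomial probit regression, and prints the longevity estimates.
"""

import numpy as np

from seedaging import DesignMatrixSpec, fit_probit, p50, paper_design, sigma_from_fit
from seedaging.simulate import simulate_lot

design = paper_design()
rng = np.random.default_rng(1)
obs = simulate_lot(ki=2.0, sigma=20.0, design=design, rho=0.05, rng=rng, lot_id="lot-A")

fit = fit_probit(obs, DesignMatrixSpec("single_lot", ("lot-A",)))
est = sigma_from_fit(fit, "lot-A")

print(f"slope            {est.slope:8.4f} probits/day  (rate of viability loss)")
print(f"sigma            {est.sigma_days:8.2f} days        (days per probit lost; true 20)")
print(f"95% CI           ({est.ci_low_days:.2f}, {est.ci_high_days:.2f}) days")
print(f"Ki               {est.ki_probits:8.3f} probits     = {est.ki_pct:.1f}% initial viability")
print(f"p50 = Ki*sigma   {p50(est.ki_probits, est.sigma_days):8.2f} days        (time to 50% viability)")
print(f"dispersion phi   {fit.dispersion_phi:8.2f}             (>1 means overdispersed dishes)")
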