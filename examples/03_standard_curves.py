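"""Estimate primer amplification efficiency from serial dilutions.

Generates noiseless and noisy 10-fold dilution series at known per-cycle
efficiencies and fits the Cq-vs-log10(dilution) line.  The efficiency is
E = 10^(-1/slope); a perfect doubling (E = 2) gives slope -3.3219 and is
reported as 100%.
"""

import pandas as pd

import refstab as rs

rows = []
for true_eff, noise in [(2.0, 0.0), (1.9108, 0.0), (2.08, 0.0), (1.958, 0.1)]:
    series = rs.simulate_dilution_series(true_eff, n_points=6, noise_sd=noise, seed=7)
    fit = rs.fit_standard_curve(series)
    rows.append((true_eff, noise, fit.slope, fit.r_squared, fit.efficiency_pct))

print(pd.DataFrame(
    rows, columns=["true_E", "noise_sd", "slope", "R2", "efficiency_pct"]
).round(4).to_string(index=False))
# Noiseless series recover the generating efficiency exactly; with 0.1-cycle
# noise the estimate wobbles by a few percent and R^2 drops below 1.
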