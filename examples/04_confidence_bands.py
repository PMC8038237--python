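"""Pointwise bootstrap confidence band for a smooth term curve.

Residual bootstrap: resample the fit's residuals, rebuild the outcome,
refit with the design and smoothing parameters held fixed, and take
pointwise percentiles of the refitted curves on a 100-point grid. The
printout shows the A1C effect curve with its 95% band; the generator's
true A1C effect peaks at 9%.
"""

import numpy as np

import tiltam as tm
from tiltam.synthetic import study_terms

cohort = tm.generate_cohort(n=1200, seed=11)
y = cohort.table["AOV"].to_numpy()
fit = tm.backfit(y, cohort.table, study_terms())

band = tm.bootstrap_band(fit, cohort.table, "A1C", n_boot=200, level=0.95, seed=5)

print(f"{band.n_boot}-replicate {band.level:.0%} band for the A1C effect")
print(f"{'A1C':>6} {'estimate':>10} {'lower':>10} {'upper':>10}")
for i in range(0, 100, 10):
    print(f"{band.grid[i]:6.2f} {band.estimate[i]:10.4f} {band.lower[i]:10.4f} {band.upper[i]:10.4f}")

peak = band.grid[int(np.argmax(band.estimate))]
print(f"\nestimated A1C effect peaks near {peak:.1f} (generator truth: 9.0)")
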