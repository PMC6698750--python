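"""End-to-end synthetic flow-cytometry pipeline: generate -> summarize -> fit -> test.

Builds two titration datasets of ~10,000 cells per sample (3 replicates x
8 doses) whose means follow a Hill curve: one with the tight distributions
of a feedback circuit (CV 0.2), one with the broad distributions of an
open-loop system (CV 1.0).  Recovers the dose-response parameters from the
per-cell data and detects the constructed 5-fold noise difference.
"""

import numpy as np

from litersim import (
    compare_cv_curves,
    fit_hill,
    fold_change,
    generate_experiment,
    hill,
    summarize_experiment,
)

doses = [0, 50, 100, 225, 500, 1000, 2000, 4095]
response = lambda u: float(hill(np.array([u], float), 100.0, 900.0, 300.0, 2.0)[0])

low_noise, _ = generate_experiment(response, 0.2, doses, replicates=3, n_cells=10_000, seed=11)
high_noise, _ = generate_experiment(response, 1.0, doses, replicates=3, n_cells=10_000, seed=12)

summ_low = summarize_experiment(low_noise)
fit = fit_hill(summ_low, n_boot=300, seed=0)
print(f"generator truth: y0=100, ymax=900, K=300, n=2.0")
print(f"recovered:       y0={fit['y0']:.0f}, ymax={fit['ymax']:.0f}, "
      f"K={fit['K']:.0f}, n={fit['n']:.2f} [{fit.ci['n'][0]:.2f}, {fit.ci['n'][1]:.2f}]")

fc = fold_change(summ_low)
print(f"fold change max/min mean: {fc.fold:.2f} (Welch t-test p = {fc.p_value:.2e})")

summ_high = summarize_experiment(high_noise)
cmp = compare_cv_curves(summ_low[["dose", "cv"]], summ_high[["dose", "cv"]])
print(f"CV contrast low- vs high-noise dataset: max fold difference = "
      f"{cmp.max_fold_difference:.2f}, Kruskal-Wallis p = {cmp.p_value:.2e}")
print()
print("The per-cell pipeline recovers the generating dose-response within its")
print("confidence intervals and flags the 5-fold noise difference as significant.")
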