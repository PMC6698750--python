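"""Dose-response shape and the noise advantage of negative feedback.

Computes the deterministic light dose-response of the TIP-LITer2.0 circuit,
fits the low-dose linear range and the full-range Hill model, and compares
single-cell noise (CV) of the feedback circuit against a mean-matched
open-loop benchmark.
"""

import numpy as np
import pandas as pd

from litersim import (
    RateParams,
    build_circuit,
    compare_noise_to_open_loop,
    dose_response_curve,
    fit_hill,
    fit_linear,
)

params = RateParams()
circuit = build_circuit("liter2", "tip", params)
doses = [0, 25, 50, 100, 150, 225, 300, 500, 750, 1000, 2000, 4095]
curve = dose_response_curve(circuit, doses)
print(curve[["dose", "gfp"]].to_string(index=False, float_format=lambda v: f"{v:9.1f}"))

lin_low = fit_linear(curve, dose_max=225.0)
lin_full = fit_linear(curve)
print(f"\nlinear fit, doses <= 225 g.s.:  R^2 = {lin_low.r2:.4f}")
print(f"linear fit, full range:         R^2 = {lin_full.r2:.4f}")

h = fit_hill(curve, n_boot=300, seed=0)
print(f"Hill fit: y0={h['y0']:.1f}  ymax={h['ymax']:.1f}  K={h['K']:.0f} g.s.  "
      f"n={h['n']:.2f} [{h.ci['n'][0]:.2f}, {h.ci['n'][1]:.2f}]  R^2={h.r2:.4f}")

cv_nf, cv_ol, mean_nf, mean_ol = compare_noise_to_open_loop(params, u=500.0, n_runs=1500, seed=0)
print(f"\nat matched mean (~{mean_nf:.0f} molecules, 500 g.s.):")
print(f"  feedback circuit CV:   {cv_nf:.3f}")
print(f"  open-loop benchmark CV:{cv_ol:.3f}   ({cv_ol / cv_nf:.1f}-fold noisier)")
print()
print("Autorepression linearizes the light dose-response (high R^2 over the")
print("whole LPA range, effective Hill coefficient near 1, no saturation by")
print("4095 g.s.) and buffers the single-cell fluctuations that the open-loop")
print("activator passes through.")
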