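"""Build a LITer circuit, inspect its reaction network, and simulate it.

Runs the single-promoter (LITer2.0) TIP circuit in the dark and under
constant light, with both engines, and prints the dark-state (basal)
reporter level, the light-induced level, and the stochastic ensemble's
agreement with the deterministic steady state.
"""

import numpy as np

from litersim import LightProgram, RateParams, build_circuit, run_ensemble, solve_steady_state

params = RateParams()
circuit = build_circuit("liter2", "tip", params)
print(circuit.describe())
print()

basal = solve_steady_state(circuit, u_const=0.0)
induced = solve_steady_state(circuit, u_const=4095.0)
print(f"deterministic basal GFP (dark):      {basal['G']:8.1f} molecules")
print(f"deterministic GFP at 4095 g.s.:      {induced['G']:8.1f} molecules")
print(f"fold induction:                      {induced['G'] / basal['G']:8.2f}")

# stochastic ensemble in the dark; long horizon so terminal states are stationary
dark = LightProgram.constant(0.0, total_duration=300.0)
ens = run_ensemble(circuit, dark, t_end=300.0, n_runs=2000, seed=1)
z = (ens.mean - basal["G"]) / ens.sem
print(f"SSA ensemble mean (n=2000):          {ens.mean:8.1f} +- {ens.sem:.1f} (z vs ODE: {z:+.2f})")
print(f"SSA population CV:                   {ens.cv:8.3f}")
print()
print("The basal level is leak-dominated; light strips TetR repression and the")
print("ensemble mean agrees with the mean-field steady state within sampling error.")
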