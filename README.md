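# litersim

Deterministic and stochastic models of **light-inducible TetR
negative-feedback ("LITer") gene circuits**, with the surrounding analysis
pipeline: illumination programs, architecture comparison experiments,
dose–response fitting, population-noise statistics, and a synthetic
flow-cytometry data generator so everything runs without external data.

## The problem

In a LITer circuit a TetR–LOV2 fusion represses both its own gene and a
GFP reporter by binding TetO operator sites; blue light unfolds the LOV2
Jα helix and exposes either a TetR-inhibiting peptide (**TIP** variant,
which abolishes operator binding) or an **RRRG degron** (which destabilises
the repressor). Light therefore *de-represses* the circuit, and the
negative feedback linearizes the dose–response and suppresses cell-to-cell
noise relative to open-loop activator systems. The package answers the
modeling questions this design raises:

- Does merging the two-promoter circuit (**LITer1.0**) into a single
  polycistronic promoter (**LITer2.0**) lower basal leakage? Under which
  parameter asymmetries (TetR lacking the reporter's intron or Kozak
  sequence: transcription or translation at 50%), and does DNA-bound TetR
  degradation matter?
- How do constant-intensity, single-pulse and duty-cycle (1 h period)
  light programs on the 0–4095 grayscale scale map to mean expression and
  noise?
- How much noisier is a mean-matched open-loop activator than the
  feedback circuit?

Models are mass-action reaction networks simulated both as ODEs (LSODA,
event-aware at light switches) and exactly with the Gillespie direct
method (numba-compiled, seeded, order-independent ensembles). Dose–response
tables are fitted with OLS on the low-dose linear range and with the
four-parameter Hill model `y(u) = y0 + ymax·uⁿ/(Kⁿ+uⁿ)` (bootstrap 95%
CIs); fold change uses Welch's t-test between extreme conditions and CV
curves are compared by Kruskal–Wallis. See `docs/methods.md` for the full
model description, parameter table and numerical policy.

## Worked example

```python
from litersim import RateParams, build_circuit, solve_steady_state, run_full_comparison
from litersim.comparison import comparison_table

circuit = build_circuit("liter2", "tip", RateParams())
basal = solve_steady_state(circuit, u_const=0.0)
induced = solve_steady_state(circuit, u_const=4095.0)
print(basal["G"], induced["G"])          # 303.2, 3772.4 molecules

reports, verdict = run_full_comparison(RateParams(), engine="deterministic")
print(comparison_table(reports)[["variant", "ratio"]])
```

which prints the five-variant basal-expression comparison:

```
          variant  basal_liter1  basal_liter2     ratio
            equal       303.232       303.232     1.000
bound_degradation       310.223       307.883     1.008
            tx_50       333.984       303.232     1.101
            tl_50       333.984       303.232     1.101
         combined       403.780       303.232     1.332
```

Read: with fully equal parameters the two architectures leak identically
(ratio 1 to 1e-6); letting DNA-bound TetR degrade breaks the equality;
halving TetR transcription+leak or translation in the two-promoter circuit
raises its basal output ~10% above the single-promoter circuit, and both
together raise it ~33% — the modeling rationale for the LITer2.0 design.
The `examples/` directory contains four narrative scripts (build &
simulate, architecture comparison, dose–response & noise, synthetic flow
pipeline); each prints its numbers with a one-line interpretation.

A thin CLI mirrors the library for shell use:

```sh
litersim simulate --config run.yaml --out out/      # trajectory / ensemble
litersim compare  --config run.yaml --out out/      # five-variant verdict
litersim scan     --config run.yaml --regime duty_titration --grid 0,0.125,0.25,1
litersim synth    --seed 1 --out data/              # synthetic per-cell CSV
litersim analyze  --cells data/cells.csv --out fits/
```

Every command writes CSV outputs plus a manifest (config, seeds, circuit
hash) sufficient to re-run it bit-identically.

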