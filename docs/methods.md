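# Models and methods

`litersim` models optogenetic negative-feedback gene circuits in which a
TetR–LOV2 fusion protein represses both its own gene and a co-regulated
reporter (GFP), and blue light relieves repression by exposing either a
TetR-inhibiting peptide (TIP) or a degradation tag (RRRG degron) hidden in
the dark-state LOV2 Jα helix. This note records the model equations and
assumptions, the default parameters and why they were chosen, what the
synthetic data generator does and does not emulate, and the numerical
choices that matter.

## Reaction networks

All circuits are mass-action reaction networks over integer copy numbers
(stochastic engine) or nonnegative reals (deterministic engine). Species
and reactions are generated programmatically per architecture and variant;
`CircuitSpec.describe()` prints the full network.

**Promoters.** Each promoter carries `n_op` TetO operator sites (default 2)
in a sequential-binding scheme. Transcription proceeds at the full rate
`a` only from the fully unoccupied state and at the leak rate `l` from any
repressed state. Binding propensity from a state with `i` repressors bound
is `k_on * (n_op - i) * [TetR_free]`; unbinding is `k_off * i`. The
repressing unit is treated as a single TetR molecule (no explicit
dimerization).

**Light.** Dark TetR converts to lit TetR at `k_act * u(t)` per molecule,
linear in the LPA grayscale setting `u ∈ [0, 4095]`; lit TetR reverts at
`k_rev` (LOV2 refolding). In the TIP variant, lit TetR cannot bind
operators and a bound TetR hit by light unbinds immediately, released in
lit form. In the Degron variant, lit TetR binds normally but carries an
extra degradation rate `d_deg` both free and on the DNA; degron promoter
states therefore track (dark-bound, lit-bound) pairs.

**Architectures.** `liter1` has two independent promoters (reporter and
repressor genes, each with its own occupancy states) competing for one
TetR pool. `liter2` has a single promoter producing one polycistronic
transcript translated into both proteins, which forces the synthesis
parameters of TetR and GFP to be equal; construction rejects unequal
values. `open_loop` is a no-feedback benchmark standing in for
activator-type systems (e.g. VVD): a two-state telegraph promoter whose
activation rate is Hill-shaped in light, `ol_act * (b + (1-b) u^h/(K^h+u^h))`,
with constant deactivation `ol_deact`. The slow ON/OFF switching is what
gives open-loop activator systems their broad expression distributions; a
lumped constant-rate model would paradoxically be *quieter* than the
feedback circuit at matched mean. This benchmark is deliberately generic
and makes no claim to VVD's dimerization mechanism.

**Bound-TetR degradation toggle.** By default DNA-bound TetR neither
degrades nor dilutes (`d_bound = 0`); this is what makes the equal-parameter
liter1/liter2 basal equality exact. Setting `d_bound > 0` adds a reaction
destroying a bound repressor and freeing its site, which turns each
promoter into a TetR sink; two promoters sink twice as much, breaking the
equality.

## Default parameters

| symbol | value | meaning |
|---|---|---|
| `a_G`, `a_T` | 1600 /h | maximal transcription rate |
| `l_G`, `l_T` | 32 /h | leak through a repressed promoter (2%) |
| `b_G`, `b_T` | 2.5 /h | translation rate per transcript |
| `d_m` | 2.77 /h | mRNA degradation (~15 min half-life) |
| `d_p` | 0.1 /h | protein degradation/dilution (~7 h half-life) |
| `k_on` | 1 /(molecule·h) | TetR–operator association per free site |
| `k_off` | 10 /h | TetR–operator dissociation |
| `n_op` | 2 | TetO sites per promoter |
| `k_act` | 0.02 /(h·g.s.) | light activation coefficient |
| `k_rev` | 2 /h | lit→dark reversion |
| `d_deg` | 2 /h | extra degradation of lit TetR (Degron) |
| `d_bound` | 0 | degradation of DNA-bound TetR (toggle) |
| `ol_K`, `ol_h`, `ol_basal` | 200 g.s., 2, 0.02 | open-loop light activation |
| `ol_act`, `ol_deact` | 0.5 /h, 0.5 /h | open-loop promoter switching |

Rationale. Timescales follow chemically inducible TetR linearizer models
(mRNA minutes, protein hours, one genomic integration). The expression
scale is transcription-dominated: large transcription rates with weak
translational amplification give basal reporter levels of ~300 molecules
with small bursts. This is a deliberate choice of regime, made once at
design time: it places the circuits where the deterministic (mean-field)
description of the nonlinear feedback is quantitatively accurate, so the
stochastic and deterministic engines agree to within sampling error at the
ensemble sizes used — the regime the comparison experiments assume. At the
defaults, basal repression is deep (occupancy ratio `k_on·TetR/k_off ≈ 29`,
so basal output is leak-dominated), dark-state basal GFP is ~303 molecules,
and constant 4095 g.s. gives ~12-fold induction with a half-maximal dose in
the few-hundred g.s. range.

A consequence worth stating plainly: the SSA's intrinsic-noise CV at the
defaults is ~0.08–0.12, smaller than typical flow-cytometry CVs, because
the mechanistic model contains no extrinsic noise (cell size, cell cycle,
instrument spread). Population-level CV magnitudes comparable to
experiments are the job of the synthetic flow generator, not the SSA.

## Engines

**Deterministic.** `dx/dt = Sᵀ a(x, u)` integrated with LSODA at
`rtol 1e-8`, `atol 1e-10`. Light programs are piecewise constant and the
solver is restarted at every switch point, so discontinuities are handled
exactly. `solve_steady_state` integrates 500 h at constant light to select
the biologically reached fixed point, then polishes it with bounded
least-squares on the rate equations augmented with the promoter
conservation constraints (the raw Jacobian is singular along conservation
laws); convergence is flagged and the residual reported. Dose–response
curves default to the terminal-time read-out of the experimental protocol
(72 h for the feedback circuits, 24 h for the open-loop benchmark); a true
steady-state mode is also provided.

**Stochastic.** Exact direct-method SSA (numba-compiled). Within each
constant-light segment propensities are time-independent; each exponential
waiting time is capped at the next light switch where propensities are
recomputed and the clock redrawn, which is exact by memorylessness.
Tau-leaping and hybrid schemes are deliberately out of scope: the networks
have ≤ ~70 reactions and exactness is preferred. Ensembles derive one
child seed per run from the master seed through `numpy.random.SeedSequence`,
so results are reproducible and independent of execution order (the first
k runs of a larger ensemble are bit-identical to a k-run ensemble). CV of
a zero-mean condition is reported as missing, not infinity. The test suite
cross-validates the engine against an independently coded next-reaction
sampler (Anderson's modified NRM, pure Python, in `tests/nrm_oracle.py`)
via a two-sample KS test.

Stochastic basal comparisons are run to a 300 h horizon rather than the
72 h experimental read-out: the comparison target is the deterministic
*steady state*, and the stochastic mean relaxes more slowly than the
deterministic trajectory (rare low-TetR excursions), so a stationarity
margin is needed. Dose–response and illumination scans keep the 72 h/24 h
terminal times. Default initial condition is the empty (zero-molecule)
state with free promoters.

## Architecture comparison experiments

`run_full_comparison` evaluates basal (dark) reporter output of both
architectures under five parameter variants: `equal`, `bound_degradation`
(`d_bound = 1/h` in both architectures), `tx_50` (TetR transcription *and
leak* at 50% in liter1 — the two are coupled because both are properties of
the same promoter/intron context), `tl_50` (TetR translation at 50%), and
`combined`. LITer2.0 keeps equalized parameters by construction. At the
defaults the deterministic liter1/liter2 ratios are 1.000, 1.008, 1.101,
1.101, 1.332. The verdict block checks the three model predictions
(equality under equal parameters, each 50% variant raising liter1 basal,
the combined variant exceeding either single change); orderings, not
magnitudes, are the scientific claim, since the ratios' sizes depend on
repression depth.

## Dose–response analysis

The linear fit is OLS on doses ≤ `dose_max` (default 225 g.s., the
instrument range where these circuits respond linearly). The Hill model is
`y(u) = y0 + ymax·uⁿ/(Kⁿ+uⁿ)` with an explicit basal term `y0`, because
uninduced expression is leak-dominated and nonzero. Initialization:
`y0 = min(y)`, `ymax = range(y)`, `K` from interpolating the half-range
crossing, `n = 2`; bounds keep all parameters positive and `n ≤ 25`.
Confidence intervals are 95% percentile intervals from a seeded
nonparametric bootstrap over (dose, value) points, default 1000 resamples
(dose grids here are ≤ 12 points, too short for asymptotic Jacobian
intervals to be trustworthy); measured coverage for the Hill coefficient
under 5% multiplicative noise is ~98/100. Fold change is max-mean over
min-mean across conditions with Welch's unequal-variance t-test between
the two extreme replicate sets (the degenerate zero-variance case returns
p = 0 or 1 by direct comparison of means). CV curves of two circuits are
compared by a Kruskal–Wallis test pooling all doses × replicates per
circuit, plus the maximal per-dose fold difference of mean CV. Raw
p-values are reported; no multiple-testing correction is applied.

Note that the mechanistic feedback circuits produce *nearly linear*
dose–responses over the whole LPA range (effective Hill coefficient ~1.2,
no saturation by 4095 g.s.) — the linearizing effect of autorepression.
The distinctly sigmoidal shapes with Hill coefficients near 2 appear in
the synthetic flow datasets, whose generating curves are Hill functions by
construction.

## Synthetic flow cytometry

`generate_sample` draws per-cell fluorescence from moment-matched families:
lognormal (default; `σ² = ln(1+CV²)`, `μ = ln(mean) − σ²/2`), gamma
(`shape = 1/CV²`), or a mixture of lognormals for bimodal/broad open-loop
populations. `generate_experiment` builds a titration dataset (default 3
replicates per dose, 10,000 cells per sample) whose sample means follow a
supplied response curve and CVs follow a CV profile; every sample's seed is
recorded in a manifest. Replicate-to-replicate spread comes from sampling
variability only — no deliberate batch effects. The generator emulates
pre-gated, right-skewed, positive fluorescence distributions anchored at
~10² a.u. basal to ~10³–10⁴ a.u. induced; it does not emulate instrument
effects (autofluorescence, spillover, debris, gating), cell-cycle structure
or temporal correlations. Tests passing on these data therefore validate
the analysis pipeline's statistics, not robustness to instrument artifacts.

## Numerical and degenerate-input policy

- ODE states are clipped to ≥ 0 inside the RHS; runaway states (> 1e12)
  abort with a diagnostic rather than letting the solver churn on overflow.
- Piecewise-constant light is never smoothed; both engines operate segment
  by segment (duty-cycle programs at 72 h have 144 segments).
- `fit_hill` refuses flat data and < 5 distinct doses; primary-fit
  non-convergence returns a flagged result with diagnostics instead of
  raising; bootstrap resamples that fail to converge are dropped and
  counted.
- `fold_change` refuses single-condition tables and < 2 replicates at the
  extremes and flags a zero minimum mean instead of dividing by zero.
- Kruskal–Wallis on two identical CV tables returns H = 0, p = 1 (scipy
  rejects all-identical input).
- Duty fraction 1 and constant light produce identical programs and
  identical results in all engines; single-run ensembles are flagged
  degenerate.

## Test problem sizes

The shipped suite runs the engine-agreement experiment at 2,000 SSA runs
per condition, the analytic Poisson oracle at 10,000 runs, the
direct-vs-next-reaction KS comparison at 2,000 runs over a 12 h horizon,
CI-coverage at 100 replicates × 300 bootstrap resamples, and the synthetic
pipeline at 3 × 8 × 10,000 cells. These sizes were chosen so each check's
Monte-Carlo resolution comfortably exceeds the effect it verifies.

## Known limitations

- TetR is modeled as a monomeric repressing unit; dimerization and
  DNA-looping cooperativity are not represented (the two-site occupancy
  scheme provides the only cooperativity).
- The light coupling is linear in grayscale units; no photon-flux
  calibration or photobleaching.
- The open-loop benchmark is a generic telegraph-promoter activator, not a
  mechanistic VVD model; only topology-level noise comparisons should be
  read from it.
- No extrinsic noise in the mechanistic model (see above); no cell growth,
  division or dilution dynamics beyond the first-order `d_p`.
- Deterministic "steady state" assumes a unique biologically reached fixed
  point selected by relaxation from the empty state; bifurcation analysis
  is out of scope.
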