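# ifascal

Automated calibration of a steady-state integrated fixed-film activated
sludge (IFAS) process model: global sensitivity screening, variance
decomposition, derivative-free parameter estimation and Monte-Carlo
uncertainty quantification, wired into one reproducible workflow.

## The problem

Biokinetic models of hybrid suspended-growth/biofilm reactors are heavily
over-parameterised: tens of kinetic and stoichiometric constants stand
behind three routinely measured effluent composites (BOD, TN, TSS).
Calibrating all of them against such data is hopeless and unnecessary —
most parameters barely move the outputs, and some move them only in
combinations that the data cannot distinguish (collinearity).  The standard
remedy is a staged workflow:

1. **Morris elementary-effects screening.** One-at-a-time trajectories give
   per-factor effects EEᵢ = (y(x + Δeᵢ) − y(x))/Δ at a cost of r(k+1) model
   runs; factors are summarised by μ*ᵢ = mean|EEᵢ| (influence magnitude),
   σᵢ (non-linearity/interaction) and ranked by B = √(μ*² + σ²).  Scores
   are min–max normalised and factors with normalised μ* ≥ 0.1 are kept;
   the top 10 per output go forward.
2. **Sobol variance decomposition.** Saltelli sampling over ±50% parameter
   ranges; first-order Sᵢ = Vᵢ/V (Saltelli-2010 estimator), total-order
   S_Ti (Jansen estimator), pairwise S_ij (cross-matrix estimator), with
   95% bootstrap confidence intervals.  Parameters with S_Ti ≥ 0.05 are
   declared influential; S_Ti − Sᵢ ≥ 0.05 or S_ij ≥ 0.05 flags
   interactions/collinearity.
3. **Nelder–Mead estimation.** The influential set is estimated jointly by
   minimising Σⱼ((yⱼ(θ) − tⱼ)/σⱼ)² — the negative log-likelihood under
   independent normal errors — with a from-scratch simplex implementation
   (reflection/expansion/contraction/shrink = 1/2/0.5/0.5, box bounds by
   projection).
4. **Monte-Carlo uncertainty.** Influential parameters get densities from
   literature ranges (uniform: u = a/√3; triangular: a/√6; normal: sample
   s.d.); propagation yields per-output combined standard uncertainty U_c
   and expanded uncertainty U_e = 1.96·U_c (95% coverage).
5. **Validation.** The calibrated model is re-run under alternative
   dissolved-oxygen regimes (0.5 and 4.5 mg/L) against independent data.

The package exercises this workflow end-to-end on a bundled reduced
steady-state IFAS model (ASM-style Gujer matrix with two-step
nitrification/denitrification, SRT-controlled suspended solids, a fully
retained attached-biomass pool seeing diffusion-attenuated oxygen, and an
ideal point-settler clarifier) and on a synthetic-observation generator, so
every stage is testable against known ground truth.  See
`docs/methods.md` for the model equations, assumptions and limitations.

## Worked example

```bash
ifascal run-all --seed 1 --sobol-n 256 --mc-n 10000 --outdir out
```

prints:

```
wrote 24 report files to out
influential: ['X52', 'X53', 'X16', 'X1', 'X21', 'X17', 'X43']
code  default  estimated  adjustment
 X52    0.666   0.668119    0.002119
 X53    0.533   0.575736    0.042736
 X16    0.620   0.570675    0.049325
  X1    4.000   4.042903    0.042903
 X21    0.900   0.867426    0.032574
 X17    0.150   0.161127    0.011127
 X43    0.500   0.479567    0.020433
BOD: 8.30 +- 2.74 mg/L (95% coverage)
TN: 18.22 +- 8.24 mg/L (95% coverage)
TSS: 35.73 +- 4.46 mg/L (95% coverage)
```

Reading this: the Morris screen of all 68 registry parameters forwarded the
top 10 per output; the Sobol stage found seven parameters with total-order
index ≥ 0.05 — led by the aerobic heterotrophic yield on soluble substrate
(X52), which dominates the BOD and TSS variance, and the anoxic yield
(X53), which dominates TN.  The simplex estimator then matched the
synthetic observation essentially exactly (the residual objective is
~1e-16; adjustments from the defaults stay small because the synthetic
truth is near the defaults), and the Monte-Carlo stage propagated the
literature-range densities of the influential parameters into 95% coverage
intervals on each effluent composite, TN carrying the largest uncertainty.
`out/` holds the full per-stage CSV/JSON reports, including Morris-plot
coordinates, the pairwise interaction matrix and distribution histograms.

The CLI verbs `characterize`, `screen`, `sobol`, `calibrate`,
`uncertainty` and `validate` run the same workflow and print the
corresponding stage's view; the library API (`ifascal.pipeline.run_pipeline`
and the per-stage modules) exposes everything programmatically.

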