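# Methods

## The reduced IFAS process model

The bundled evaluator is a deliberately reduced steady-state model of a
hybrid suspended-growth/biofilm (IFAS) reactor followed by a clarifier.
It exists to give the calibration pipeline a realistic, fast,
fully-auditable simulator; it is not a substitute for a research-grade
biofilm model, and its limitations are listed at the end.

### States and processes

Bulk concentrations (g/m³): soluble S_S (readily biodegradable COD), S_I
(inert), S_NH, S_ND, S_NO2, S_NO3, S_N2; suspended particulates X_S
(slowly biodegradable), X_I (inert), X_ND (organic N), X_BH (heterotrophs),
X_BA1 (ammonia oxidizers), X_BA2 (nitrite oxidizers); attached pools A_BH,
A_BA1, A_BA2 expressed per reactor volume.  Dissolved oxygen is a fixed
setpoint, not a solved state (the plant operates at DO setpoints), but it
carries an explicit stoichiometric column so conservation checks close.

The Gujer matrix (one definition file, `src/ifascal/stoichiometry.py`)
contains, per biomass pool: aerobic heterotrophic growth (yield X52),
anoxic growth on NO3 and on NO2 (yield X53; the NO2 pathway scaled by the
reduction factor X12, the NO3 pathway by its own factor; oxygen inhibition
switch K_O/(K_O + S_O) with K_O = X15), death–regeneration decay (rate
X16, inert fraction X61 to X_I, remainder to X_S), two-step nitrification
(AOB growth NH4→NO2; NOB growth NO2→NO3 at μ_max = X27), autotroph decay;
plus hydrolysis of X_S and X_ND mediated by total heterotrophs,
ammonification of S_ND, and attachment/detachment exchange between the
suspended and attached pools.  Electron-acceptor equivalents are exact
fractions — 40/14 ≈ 2.86 gCOD/gN for NO3→N2 and 24/14 ≈ 1.71 gCOD/gN for
NO2→N2 — so that every process row conserves COD and N to 1e-10, which the
test suite asserts.

### Hydraulics and the attached pool

Solubles obey CSTR balances at dilution rate Q/V; suspended particulates
are removed at 1/SRT (wastage plus effluent escape); attached pools have no
hydraulic loss.  The attached compartment is a capacity-capped biomass pool
sharing bulk substrate: growth and attachment scale with the free capacity
φ = 1 − ΣA/A_cap.  Two deliberate design choices here:

- **Attachment/detachment exchange** (k_att = 0.5/d, k_det = 0.05/d)
  rather than a pure capacity cap.  A pure cap makes multi-species
  coexistence on the media a degenerate equilibrium (each species would
  need growth·φ = decay simultaneously); the exchange terms make the
  steady state well-posed and are standard in simple biofilm links.
- **Diffusion-attenuated oxygen in the biofilm**: the attached pool sees
  0.05 × bulk DO.  This emulates biofilm-interior anoxia and the
  simultaneous nitrification–denitrification that fixed-film systems
  exhibit; without it a bulk-DO-everywhere model cannot remove total
  nitrogen under full aeration at anything like the observed rate (the
  bundled fixture's effluent TN would sit near 28 mg/L instead of ~12.5
  against an observed 14.0).

The clarifier is an ideal point-settler: a non-settleable fraction
f_ns = 0.005 of mixed-liquor solids leaves with the effluent, the rest is
routed to the underflow; conservation is exact.

### Effluent composition

BOD = f_BOD · (S_S + f_ns · biodegradable particulate COD) with
f_BOD = 0.66; TN = S_NH + S_ND + S_NO2 + S_NO3 + N bound in escaping
particulates (biomass N content i_XB, inert content i_XU); TSS = escaping
particulate COD / 1.48 (COD:VSS) / 0.63 (VSS:TSS).  Influent fractionation
defaults: S_S/X_S/S_I/X_I = 20/50/5/25% of total COD, organic N split
40/60 soluble/particulate, TN − TKN assigned to influent nitrate.  All
conversion factors are configurable per plant config.

### Steady-state solver

Damped Newton on the algebraic balances (finite-difference Jacobian
evaluated in one batched call, LU factorisation reused while the residual
contracts strongly), positivity enforced by projection, absolute residual
tolerance 1e-10, 500-iteration cap.

Two non-trivial behaviours shape the solver design.  First, growth
incorporates nitrogen (i_XB per unit biomass), so every growth rate
carries a small-K ammonia nutrient switch (K = 0.05 mgN/L); without it
the ammonia balance has no nonnegative solution at high-yield corners of
the screening ranges.  Second, the system can be *bistable*: attachment
losses to an empty biofilm make total washout locally stable for some
parameter draws even though an active (coexistence) branch exists.  The
evaluator convention is the branch the dynamics reach from a standard
inoculated seed.  Cold starts therefore follow a flow-faithful
pseudo-transient continuation (approximate backward-Euler whose step is
rejected and shrunk whenever it would flip a live biomass pool to zero —
the signature of a step that over-runs an unstable growth mode and hops
into the washout basin), with Newton polishing attempts in between; a
Newton result that kills a species the flow still carries is rejected and
the flow continued.  Batch evaluations warm-start from the steady state at
registry defaults — the same point for every row, which keeps results
independent of evaluation order and bit-reproducible; a warm result that
lands on total washout or on a washout that could regrow is re-solved
along the flow.  Washout reached by the flow itself is a valid steady
state, never an error.  The solver is verified against an independent
oracle — long-horizon stiff ODE integration of the same balances — to
1e-6 relative on every state over random parameter draws.

## Parameter registry

68 entries with codes in the vendor style (X52 aerobic yield 0.666, X53
anoxic yield 0.533, X16 decay 0.62 1/d, X12 nitrite-denitrification factor
0.48, X15 oxygen-inhibition 0.2 mgO2/L, X61 inert decay fraction 0.08, X27
NOB μ_max 0.7 1/d, plus 21 further active kinetic/stoichiometric constants
with conventional activated-sludge defaults).  The remaining 40 entries are
inert padding marked `kind=padding`: the full 68-parameter listing of the
source system is not public, and the padding preserves the screening
problem's dimensionality honestly — their elementary effects are exactly
zero, so they rank at the bottom by construction.  Screening/decomposition
ranges are ±50% of each default; registry bounds additionally cover the
literature ranges used by the uncertainty stage (X16's bound is widened to
0.23 for that reason).

## Sensitivity, estimation and uncertainty stages

- Morris: p = 4 grid levels, Δ = p/(2(p−1)) = 2/3, plain random
  trajectories; elementary effects computed in unit-hypercube coordinates
  so μ* is range-scaled and comparable across factors.  σ uses the sample
  standard deviation (divisor r−1).  Trajectories containing any
  non-finite output are dropped whole; >20% dropped is refused.
  Normalised μ* ≥ 0.1 (inclusive) marks influence; ties in B break by μ*,
  then registry order.
- Sobol: scrambled Sobol'-sequence Saltelli design (n(2k+2) rows with
  second-order blocks), Saltelli-2010/Jansen/cross-matrix estimators,
  percentile bootstrap over base samples with the resample applied
  block-consistently.  Failed evaluations drop their base sample across
  all blocks (≤5%).  Negative small estimates are reported as-is and
  flagged below −0.05.
- Nelder–Mead: standard coefficients, initial simplex at +5% of each
  coordinate's range (inward at a bound edge), termination on relative
  vertex spread < 1e-8 (the value-spread criterion is available but
  disabled by default — on symmetric 1-D objectives it can fire at
  equal-valued vertices straddling the minimum).  Bounds by projection;
  a quadratic-penalty mode is available.  Evaluator failures are charged a
  large penalty rather than raised.
- Uncertainty: uniform densities over bundled literature ranges for the
  four headline parameters (X12's range 0.375–0.48 encodes the
  equal-NO2/NO3 split of reported total denitrification factors); other
  influential parameters fall back to ±50% of default.  U_e = 1.96·U_c
  exactly; n = 1e4 in bundled runs, 1e5 where the evaluator is trivial.

## The synthetic-observation generator

Observations are the model's three outputs at a known truth θ* — defaults
perturbed in the four headline parameters to (0.65, 0.52, 0.51, 0.39) —
plus independent normal noise at 2% of each output (zero-truncated),
seeded.  What passing tests show: the stages are numerically correct, the
workflow is deterministic under one master seed, and the identifiable
parameter combinations are recovered.  What they cannot show: anything
about real measurement error structure (correlated sampling campaigns,
composite-sample bias), or about fidelity of the reduced model to a real
plant.

## Known limitations

- Three effluent composites cannot uniquely determine four or more jointly
  calibrated parameters: the 3×k output Jacobian necessarily has a null
  space for k ≥ 4, and on this model the (X53, X16, X12) directions are
  strongly collinear in their effect on TN.  The simplex lands on an
  exact-fit point that can sit well away from θ* along those directions.
  This is precisely the practical non-identifiability the variance stage
  is designed to expose (and on this model X12 indeed falls below the 0.05
  total-order threshold).  Consumers should treat the calibrated values of
  collinear parameters as one identified combination, not as individually
  meaningful estimates.
- The validation regimes stress exactly the physics the stand-in
  simplifies (oxygen transport into the biofilm), so its low-DO predictions
  overstate performance substantially; the bundled validation table is
  reported, not asserted.
- No pH/alkalinity chemistry, no temperature correction of kinetics, no
  settler flux theory, no dynamic simulation as a user feature (ODE
  integration exists only as the test oracle).
- Mixed-liquor solids at the bundled fixture settle out near 6–7 g/L
  rather than the plant's reported 2 g/L: with the declared influent
  fractionation the inert load times SRT/HRT is simply larger than the
  reported inventory; the discrepancy is documented rather than hidden by
  re-tuning fractions.

## Problem sizes used in bundled runs

Morris r = 100 over k = 68 (6900 evaluations); Sobol n = 256 base samples
per output over the forwarded top-10 (5632 evaluations each, second order
included); bootstrap 100–200 replicates; Monte-Carlo n = 1e4 on the
process model and 1e5 on closed-form checks; test-suite runs use smaller
r/n since the statistical assertions there are tolerance-based.
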