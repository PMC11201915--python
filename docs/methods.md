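# Methods

This note documents the models implemented in `combifit`, the assumptions
behind them, what the synthetic-data generator does and does not emulate,
and the numerical and design choices that were genuinely open.

## Median-effect dose–response (`combifit.dose_response`)

Single-agent viability is modelled by the median-effect equation
`fa/fu = (D/Dm)^m` (`fa` fraction affected, `fu = 1 − fa`).  Taking log10
of both sides linearizes it, and `m` (slope) and `Dm` (median-effect
dose) are estimated by ordinary least squares of the logit of `fa` on
log-dose.  Base-10 logarithms are used throughout, matching the
convention of the CI-analysis software ecosystem.  The EC50 is *defined*
as `Dm` of this fit rather than by interpolation; this keeps the EC50 and
the combination-index machinery on one model.

Choices:

* **Replicates are averaged per concentration before the logit
  transform.**  Assay results are reported as mean ± SD per dose, and the
  logit of a mean is better behaved than the mean of logits for viability
  values near the boundaries.
* **Clamp ε = 1e−4.**  `fa = clamp(1 − viability/100, ε, 1 − ε)` keeps the
  logit finite for viabilities at or beyond 0 %/100 %.  Points sitting at
  the clamp are *excluded* from the regression: they carry no
  dose–response information and, at extreme logit values, would otherwise
  dominate the fit through leverage.
* **Usability flag.**  A fit with non-positive slope or fewer than two
  usable points is flagged unusable rather than raising, because a flat
  curve is the *expected* outcome for a non-toxic agent (BP) and is
  consumed as such downstream.

## CCD and response surface (`combifit.rsm`)

The two-factor central composite design uses the five uniformly spaced
levels per factor: factorial points at levels 2 and 4, axial points at
levels 1 and 5, and a level-3 center replicated six times — 14 runs.
With uniform five-level spacing the axial points sit at twice the
factorial half-range, so the coded axial distance is α = 2; the rotatable
α = √2 cannot land on a uniform five-level grid, and 6 center runs is the
only partition of 14 consistent with 4 + 4 factorial/axial points.

The full quadratic is fitted by least squares **in coded units** (for
conditioning) and coefficients are reported in both coded and natural
µg/mL units via the exact affine re-expansion; predictions from the two
parameterizations agree to machine precision.  Diagnostics follow
design-of-experiments practice: the residual sum of squares is split into
lack of fit and pure error (replicate-only variation within identical
factor settings), with the lack-of-fit F-test against pure error;
adjusted R²; CV% = 100·√MSE/ȳ; and Adeq Precision
`(max ŷ − min ŷ)/√(p·MSE/n)` with p = 6 parameters at the n design
observations.  Rank-deficient model matrices raise an error naming the
first aliased term (detected by incremental column rank).

Prediction outside the design region is an extrapolation of a quadratic
and degrades fast: within 5 % of the region span beyond an edge the
package warns; beyond that it raises.

## Desirability optimization (`combifit.desirability`)

Derringer target transform per response (linear ramps by default,
exponents `s`, `t` configurable), combined by geometric mean.  Choices
where the published workflow leaves the settings unstated:

* **Bounds L, U default to the min/max predicted response over the design
  region** (per response) when only a target is supplied — the default
  behaviour of DOE optimization software.  The package also accepts
  explicit bounds.
* **Weights s = t = 1** (no weighting is mentioned anywhere upstream).
* **Search**: a 201×201 grid pass (sub-0.5 % resolution per axis), bounded
  Nelder–Mead polish from every grid-local maximum, and — when every goal
  is a target goal for two responses — an exact joint-target refinement
  that solves `Y_i(tm, bp) = T_i` directly.  The refinement means an
  attainable joint target yields D = 1 to machine precision rather than
  D ≈ 0.9999 from a numerically polished maximum.
* **Ties break toward the lower total concentration** (pharmacological
  parsimony, and it makes the ranking deterministic); solutions are
  deduplicated at 0.5 % of the region span.

## Combination index (`combifit.synergy`)

`CI = d1/Dx1(fa) + d2/Dx2(fa)` evaluated at each combination's own
observed `fa` (non-constant-ratio analysis: the tested combinations — a
fixed TM dose with varying BP plus one optimized pair — are not a
fixed-ratio dilution series).  The non-toxic partner is handled by the
classical `Dx2 → ∞` limit: its term is dropped and the result flagged
`partner_nontoxic`.  This is the conservative reading under which CI < 1
still means the partner potentiates the primary agent.  An agent is
auto-flagged non-toxic when its median-effect fit is unusable or its
largest replicate-mean `fa` over the tested range stays below 0.2
(configurable).  Classification uses a ±0.05 additive band around CI = 1
(configurable): CI is a continuous score and hairline deviations from
unity should not flip the label.

## Consumption kinetics (`combifit.kinetics`)

The decay signal is regressed linearly on time using **all replicate
points** (replicate means are optional); `Abs0` is the **regression
intercept**, not the earliest measured value, since the rate formula is
defined from the fitted line.  `σCC = −σAbs·N0/Abs0` is invariant to the
signal's unit (slope and intercept scale together), so peak areas,
absorbances or concentrations all work.  Activity
`(σCC − σCC,blank)/CCmass` may be negative when the blank decays faster
than the sample; it is reported with a warning rather than floored,
because that situation is an informative QC signal.

Default dosing constants: the TM extract carries 26.7 µg curcumin per mg
extract, so at the optimal TM dose (48.5 µg/mL) one mL of medium holds
`CCmass = 1.295 µg` ≈ `N0 = 3.515 nmol` of curcumin (M = 368.38 g/mol).
The absolute scale of a reported activity depends on the volume/mass
convention chosen for `N0` and `CCmass`, which is configurable; the
blank-corrected *ordering* between conditions does not.

## Synthetic data (`combifit.synthetic`)

The generator emulates the statistical structure the estimators assume:

* **Single agents**: mean viability `100·(1 − fa(D))` with `fa` from the
  median-effect equation.  TM ground truth: EC50 77.8 µg/mL on A549 and
  92.0 µg/mL on NCI-H292 with slope m = 2 (a free choice of typical
  steepness for crude-extract cytotoxicity; the assays report mean ± SD
  only), and a resistant normal fibroblast line (m = 4, Dm = 250 µg/mL)
  that only responds near the top of the tested range.  BP is nearly flat
  (8 % effect at 400 µg/mL, linear in dose).
* **Combination surface**: a quadratic ground truth per cell line over
  TM 10–50 × BP 200–400 µg/mL, anchored so both responses equal exactly
  50 % viability at (48.5, 241.7) µg/mL.  The A549 surface is driven
  mainly by TM with accelerating potency (negative TM curvature), the
  NCI-H292 surface mainly by the BP axis; the two 50 %-contours therefore
  cross transversally and only once inside the region.  The crossing
  point of *re-fitted* surfaces is a stochastic quantity: under the
  default 5 % replicate noise it stays strictly inside the concentration
  window in roughly 85 % of seeds (measured over 100 seeds), slipping
  past the nearby TM = 50 edge otherwise; the default scenario (seed 0)
  is interior.  Tests of the interior-optimum property therefore pin the
  default scenario.
* **Time courses**: linear decay of a curcumin signal with fractional
  rates 0.5 %/h (abiotic blank), 5.5 %/h (cells + TM) and 2.65 %/h
  (cells + TM + BP), reproducing the slowed-consumption ordering under
  the combination.  The magnitudes printed for this system upstream are
  not dimensionally reconcilable with a linear signal that stays positive
  over the 2–10 h window, so the generator reproduces the ordering and
  the qualitative effect size, not those absolute magnitudes.
* **Noise model**: replicate values are `mean × (1 + ε)`,
  `ε ~ N(0, cv)` — multiplicative because assay CVs scale with signal —
  clipped to [0, 120] % viability (plate readers report super-100 %
  values but not unbounded ones).  Default cv = 0.05 and 3 replicates,
  the reporting convention of triplicate neutral-red assays.
* **Determinism**: every table draws from an RNG substream keyed by
  (seed, table kind, labels), so any single table can be regenerated
  bit-identically in isolation.

What the generator does **not** emulate: plate-layout and edge effects,
chromatographic peak shapes, absorbance non-linearity, between-day batch
effects, or heavy-tailed outliers.  Passing tests therefore demonstrate
the correctness and calibration of the estimators under the assumed
noise model, not robustness of the laboratory workflow to artifacts the
model excludes.

## Problem sizes and tolerances

Test and pipeline runs use the study-scale inputs throughout: 14-run
designs, 3 replicates, 5–6-point dose panels, 5 time points.  Monte-Carlo
checks use 200 seeds (recovery calibration) or 500 seeds (coefficient
unbiasedness); the desirability optimizer is validated against a
2000×2000 grid oracle.  Noiseless round-trips are asserted at 1e−6–1e−9;
oracle equivalences at 1e−9 relative; the coefficient-unbiasedness check
bounds each coded coefficient's mean bias by 2 % of the largest
non-intercept coefficient, the tightest bound resolvable at 500
replicates for coefficients that are themselves near zero.

## Known limitations

* The raw CCD response data of the motivating study are not public, so the
  response-surface diagnostics (lack-of-fit p, adjusted R², Adeq
  Precision) are computed but cannot be compared against published
  values, and the generator's surface curvatures are package choices.
* No 4PL/5PL dose–response alternatives, no dose-reduction index,
  isobolograms, or Bliss/Loewe/HSA models, no Box–Behnken or D-optimal
  designs, and no Michaelis–Menten kinetics — the chain deliberately
  mirrors one published workflow.
* The desirability optimizer handles box bounds only (no constraints, no
  Pareto front).
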