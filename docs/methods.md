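# Methods

`maxhab` re-implements, as a tested and reusable pipeline, the standard
presence–background workflow used to map climatically suitable habitat for
a species (the motivating case is the subtropical Chinese tree
*Chengiodendron marginatum*): occurrence thinning, collinearity-aware
variable selection, a maximum-entropy suitability model, multi-scenario
projection, suitability-class area accounting, and centroid-migration
tracking. Because the real inputs (global bioclimatic, soil, and
topographic rasters plus curated herbarium records) are large external
downloads, the package ships a synthetic-scenario generator with exact
ground truth, so every stage is testable offline.

## The model

The core is the maximum-entropy (Maxent) presence–background model. Given
presence feature vectors `f(x)` and a background sample of `B` cells, the
model is the Gibbs distribution over background

    p(x) = exp(lam . f(x)) / Z,

fitted by minimizing the convex L1-regularized objective

    J(lam) = -mean_presence[lam . f] + log mean_background[exp(lam . f)]
             + sum_j beta_j |lam_j|,

with `beta_j = beta_multiplier * s_j / sqrt(m)`, where `s_j` is the
feature's standard deviation over the `m` presences (floored at 1e-3).
This preserves the shape of Maxent's regularization (features that vary
more among presences get more slack; more presences mean less shrinkage)
behind a single `beta_multiplier` knob rather than Maxent's per-class
default tables, which keeps the penalty auditable. Feature classes are
linear, quadratic, and hinge by default (forward and reverse hinges at 15
background quantiles per variable); product and threshold features are
available but off by default because they bloat small problems. All
feature scaling and knots come from the background sample only, so a
fitted expansion projects unchanged to other scenario stacks; projection
values are clamped to the training range by default.

Optimization is cyclic coordinate descent with GLMNET-style
soft-threshold Newton steps, backtracking on the true objective, and an
active-set refinement between full passes. Convergence is declared when a
full cycle decreases the objective by less than `tol` (default 1e-7);
non-convergence within `max_iter` cycles (default 500) is an error, not a
warning. Coordinate descent was chosen over quasi-Newton deliberately:
the sequential per-feature objective decreases are exactly the
"gain increments" that percent-contribution accounting credits to each
feature's source variable, so the diagnostic falls out of the optimizer
rather than being bolted on. Convexity means the reached objective is
unique; a unit test verifies agreement from two initializations to 1e-6
and, with the penalty off and linear features, agreement with a generic
convex solver and the KKT moment-matching condition to 1e-6.

The training gain is the improvement in mean presence log-likelihood over
the uniform background distribution (nats). Output transforms follow
Maxent 3.4.4 conventions: `raw` is the normalized density (sums to 1 over
the training background), and with `H` the entropy of the fitted
background distribution, `logistic = e^H r / (1 + e^H r)` and the default
`cloglog = 1 - exp(-e^H r)`.

## Pipeline conventions

- **Grids.** ESRI ASCII rasters, corner-registered (the `xllcenter`
  dialect converts on read), row 0 northernmost, half-open cell intervals
  with the outer north/east edge clamped inward. Cell areas are spherical,
  `R^2 * dlambda * (sin phi_n - sin phi_s)` with `R = 6371.0088` km —
  the error against an ellipsoid is far below the two-decimal precision
  of the reported area tables, and the closed form doubles as the test
  oracle. Geodesic areas are the default; a planar mode is not offered.
- **Occurrences.** Cleaning removes, in order: records with missing or
  unparseable coordinates; out-of-range or exactly-(0,0) coordinates;
  exact coordinate duplicates (first kept); and points outside the study
  bounds or mask. Each rule logs a count and the counts must reconcile
  with input/output sizes. Thinning keeps the first record per cell of a
  2.5-arc-minute grid anchored by default at the environmental grid's
  lower-left corner; first-kept is deterministic and order-auditable.
- **Variable selection.** A preliminary model on all candidates supplies
  percent contributions; pairs with `|r| >= 0.8` are then resolved
  greedily in descending `|r|` (ties by name), dropping the
  lower-contribution member (ties drop the alphabetically later name).
  Correlations are computed by default on the uniform background sample
  of the study region. Computing them at the occurrence points is
  available as `correlation_scope: occurrences`, but is not the default
  for a substantive reason: for a range-restricted species the presence
  sample truncates the environmental axes, and restriction of range
  attenuates correlations (the planted r = 0.9 pair in the synthetic
  system drops to roughly 0.77 at presences), so genuinely redundant
  pairs escape pruning exactly when the model is good.
- **Evaluation.** Seeded k-fold cross-validation (default k = 10) of the
  presences against a shared background sample (default 10,000 uniform
  cells; background is not re-sampled per fold). AUC is the rank-based
  Mann–Whitney estimator with ties counted one half. The summary
  suitability map is the arithmetic mean of the per-fold rasters.
- **Importance diagnostics.** Percent contribution (gain-increment
  credits, product features split evenly, floored at 0, normalized to
  100); permutation importance (training-AUC drop after permuting one
  variable jointly across presences and background, floored at 0,
  normalized to 100); jackknife with-only/without training gains on the
  final variable set.
- **Habitat products.** Four bands with left-closed/right-open breaks at
  0.25/0.50/0.75 and the top band closed at 1. "Suitable" everywhere
  means any class >= low. Areas are reported in 1e4 km^2 rounded
  half-away-from-zero to two decimals, and percent changes are computed
  from those printed-precision areas so the table is internally
  consistent the way published tables are. Centroids are area-weighted
  means of suitable cell centers (binary mode default; a
  suitability-weighted mode exists); displacements are haversine
  distances with initial bearings.
- **Determinism.** One global seed fans out through
  `numpy.random.SeedSequence(seed).spawn` to the background sample, the
  fold partition, and the permutation test, in that fixed order. Reruns
  with the same config and seed are byte-identical, and the run manifest
  records every output file with a SHA-256 hash.

## The synthetic study system

The generator emulates what the real study downloads. Each variable is
seeded white noise smoothed by a separable moving average (default width
5 cells) and standardized; planned pairwise correlations are imposed by
linear mixing `y = r x + sqrt(1 - r^2) z`. The default system is a
100 x 100 grid of 0.05-degree cells anchored at (100 E, 20 N) — a
subtropical-China-scale window — with six variables, one planted r = 0.9
pair (env1, env2) of which only env1 is causal, coefficients
(5.0, 0, 1.6, -1.2, 0.8, 0), intercept -8, a cloglog link matching the
model's default output family, and 200 presences drawn without
replacement with probability proportional to suitability times cell
area, placed at cell centers so thinning behavior is exactly
predictable. The intercept/coefficient scale makes the species
range-restricted (about a tenth of the window suitable, comparable to
the motivating species' share of its study region) with a sharp
response; a flat, widespread surface caps the achievable AUC near 0.75
regardless of the estimator, which would say nothing about model
quality. Two scenarios shift the dominant driver down by 0.15 and 0.4
standardized units (with small positive shifts on env3), inducing known
mild and strong contractions.

What the generator does *not* emulate: realistic GCM spatial structure,
soil-class semantics, sampling bias, or observation error. Passing tests
therefore demonstrate correct mechanics and recoverability of a known
signal, not performance on biased herbarium data.

## Known limitations

- **Cloglog area inflation.** The entropy-scaled cloglog transform
  embeds a prevalence assumption; even with a perfect density estimate
  it overstates the suitable area of the default synthetic species by
  about 15%, and finite-sample smoothing of a sharp response widens this
  substantially (the fitted 200-presence model overstates total suitable
  area by roughly 70%, insensitive to the regularization multiplier).
  Percent *changes* between scenarios are far more reliable because the
  calibration bias largely cancels: the pipeline recovers the truth's
  -20%/-50% scenario contractions within a few points. Absolute areas
  from any presence-background model should be read as index values, not
  census figures.
- Reported "optimal ranges" from response curves depend on the chosen
  suitability level (default 0.5); no claim is made that a particular
  level reproduces published habitat-optimum intervals.
- The solver targets auditable correctness, not Maxent-Java bit
  equivalence; per-feature-class default beta tables, MESS maps, and
  transfer diagnostics beyond clamping are out of scope.
- Spherical-Earth geometry and non-wrapping longitudes restrict the
  tooling to regional windows away from the antimeridian.

## Problem sizes used in the test suite

Unit tests run on toy grids (tens of cells) with closed-form or
brute-force oracles. The statistical acceptance checks run the full
pipeline on the default 100 x 100 system over five seeds (10-fold
cross-validation, jackknife on the kept variables), which completes in a
few minutes on one CPU; these sizes are the package's chosen study
conditions for the synthetic system.
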