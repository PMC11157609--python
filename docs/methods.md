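# Methods

This note documents the models, algorithms, numerical choices and known
limitations of nichecast, in the order the pipeline runs them.

## Synthetic study worlds

Every downstream stage is exercised against generated climate stacks
with known structure, so correctness can be judged against ground truth
rather than plausibility.

**Climate fields.** Each layer is a Gaussian random field: white noise
smoothed with a Gaussian kernel (`smoothing_length` in cells, default
3–4) and standardised.  The smoothed fields are then *exactly
decorrelated* (whitened) over the grid before being mixed with a
symmetric PSD square root of the target correlation matrix.  Without
whitening, smoothing shrinks the effective sample size enough that the
realized cross-correlations scatter around the targets by several
hundredths even on a 200 × 200 grid; whitening makes the whole-grid
correlation exact, while the correlation over the valid (unmasked)
subset still deviates slightly and is what the tests measure.  An
eigen-based square root is used rather than Cholesky so singular
targets (e.g. a perfect correlation of 1) are accepted.

**Latitudinal trends.** Each layer spec optionally carries a linear
trend in its mean (units per degree latitude).  Real bioclimatic
temperature layers decrease strongly poleward; this trend is what makes
a warming scenario *relocate* the thermal optimum north rather than
merely rescaling values, and it is deliberately part of the packaged
study conditions.  Units follow the WorldClim convention: temperature
in °C × 10, precipitation in mm.

**Scenarios.** A future stack shifts temperature-tagged layers by
`warming_at_equator + gradient · |latitude|` (warming intensifies
poleward) and multiplies precipitation-tagged layers by
`1 + precip_fraction`.  The packaged strong scenario uses a 5.2%
precipitation increase and warming of 1.6–2.9 °C across the domain,
the magnitude range projected for the region the synthetic world
emulates.  The transform is deterministic; layer tagging (temperature /
precipitation / other) is carried as metadata and inferred from
bioclim-style names when not given.

**Occurrences.** Presence-only points are drawn from valid cells with
probability proportional to true suitability, placed at cell centers
with a small uniform jitter.  No observer bias is modelled: real
herbarium/database records oversample cores and roads, so passing tests
here show correctness under idealized sampling, not robustness to
survey bias.  The true niche is an inverse-logit quadratic, guaranteed
in [0,1] for any finite input.

**Packaged world.** 96 × 80 cells of 0.25° spanning 100–120°E,
18–42°N; six layers named bio01/03/06/07/12/14 with two pairs above
|r| = 0.8; a temperature-limited niche with optimum at a minimum winter
temperature of 5 °C and 1400 mm annual precipitation, occupying ~7% of
the land area; 200 presence points.  The niche breadth was set so the
synthetic focal species is range-restricted like a subtropical
forest-pest system: its true-niche AUC ceiling is ≈0.97 and fitted
ensembles score ≈0.93, the regime typical of well-performing
presence-only models.  A broad generalist niche has a much lower AUC
ceiling regardless of model quality, which is a property of AUC on
presence-background data, not of the model.

## Occurrence preparation

Cleaning follows the standard sequence: exact-coordinate duplicates
(coordinates compared after rounding to 6 decimals, ~0.1 m) are removed
first, then points outside the grid or on nodata ("sea") cells, then
one point per occupied cell — the first in input order, a documented
tie-break that makes runs reproducible.  Cell membership uses half-open
intervals anchored on the raster's south-west corner, i.e. thinning is
performed on the environmental raster's own grid.  Replicate splits
follow the classic MaxEnt "bootstrap" convention: training presences
are a with-replacement resample of round(0.75 n), the test set is every
point never drawn; each replicate re-randomizes from its own seeded
sub-stream, and a replicate whose test set comes up empty is re-drawn a
bounded number of times.

## Variable screening

"Contribution" is permutation importance on training gain: one
default-settings model is fitted on all variables, then each variable's
values are permuted across the background (k = 5 permutations), the
features re-expanded, and the mean gain drop recorded; negatives are
truncated at zero and the table renormalized to 100%.  The historical
MaxEnt "percent contribution" is path-dependent on that
implementation's training trajectory and cannot be reproduced outside
it; permutation importance measures the same quantity and is
deterministic given a seed.  Pearson correlations are computed over a
seeded sample of environment cells (not presence cells), zero-variance
layers reported as undefined.  Screening drops zero-contribution
variables first, then scans |r| > 0.8 pairs in descending |r|, dropping
the lower-contribution member (ties: keep the alphabetically first);
the retained set provably contains no violating pair and every drop is
logged with its reason.

## The maximum-entropy model

Features: linear, quadratic, pairwise product, threshold steps, and
forward/reverse hinge ramps of the min–max-scaled variables (scaling
ranges from the training background; threshold/hinge knots evenly
spaced, 50 per variable per direction by default, fewer on small
problems — the pipeline uses 10).  Feature order is deterministic
(class, variable name, knot).

Penalties: β_j = RM · β_class(n) · sd_j(presence features)/√n with the
per-class base tables (linear/quadratic/product decreasing with sample
size, hinge constant 0.5, threshold larger) shipped as an explicit,
linearly interpolated config; a 10⁻⁶ floor on sd_j keeps
constant-on-presence features penalized.

Solver: FISTA proximal-gradient ascent with backtracking line search
and adaptive restart; soft-thresholding produces exact zeros, so the
AICc complexity k is well defined.  Convergence requires both a
relative objective change below 10⁻⁸ and a stationarity (KKT) gap
within 10⁻⁵, within 5000 iterations; non-converged models are flagged
and excluded from calibration.  On tiny problems the solver is verified
against dense grid searches over the penalized objective.

Outputs: raw densities normalized over the training background (they
sum to 1 there by construction, tolerance 10⁻⁹); logistic output with
prevalence fixed at 0.5 (p = e^H q/(1+e^H q)); projections clamp
variables to the training range by default before feature expansion.
The background is a seeded uniform sample of up to 10,000 valid cells
(2,000 in the desk-scale runs) with all presence cells always included
in the normalization set.  The entropy-maximization formulation is
implemented in its standard unconditional presence-only
specialization — occurrence data has no response classes, so the
conditional form collapses to a single distribution over cells.

## Calibration and selection

The candidate grid is the Cartesian product of the RM ladder (0.1–4.0
step 0.1 at the defaults, values rounded to one decimal) and 29 feature
combinations — all non-empty subsets of {L,Q,P,T,H} minus the two
rarely-meaningful singletons {P} and {T}; the list is config-replaceable.

Each candidate is fitted on a seeded 75/25 split and scored by:

- **AICc** — raw output renormalized over all valid calibration cells,
  lnL summed at presence cells, k = nonzero coefficients, with the
  small-sample correction; candidates with n − k − 1 ≤ 0 get +∞.
- **Omission at E = 5%** — threshold is the E-quantile (lower method)
  of training-presence suitability; the rate counts test presences
  strictly below it.
- **Partial-ROC significance** — the (proportion of predicted area,
  sensitivity) curve restricted to omission ≤ E, with the left endpoint
  interpolated at sensitivity 1 − E; each of 500 iterations bootstraps
  50% of the test presences and the AUC ratio compares the model curve
  with the null diagonal over the same span; p = fraction of ratios
  ≤ 1.  A constant raster has no curve and fails by convention.  The
  ratio estimator carries a mild upward bias at the restriction
  boundary (a null model's p-value sits near 0.1 rather than 0.5);
  what matters for the protocol is that a null model never clears
  p < 0.05, which holds with margin.

Selection filters in order: converged → significant (p < 0.05) →
omission < 5% → minimum AICc, with ΔAICc recomputed among the final
survivors so the chosen model has ΔAICc = 0 exactly; ties break by
smaller k, then smaller RM, then feature-combination name.  An emptied
filter is skipped with a logged warning rather than aborting.

**Split re-draws.** Because train and test presences are exchangeable,
the expected omission rate sits almost exactly at E; on a small test
set a reduced grid of smooth candidates (whose suitability rankings are
nearly identical) can therefore leave the omission filter empty through
split luck alone — a single binomial draw shared by all candidates.
The full 1160-candidate grid with hinge/threshold features effectively
always has survivors; the desk-scale grid does not.  `calibrate`
therefore re-draws the 75/25 split up to 5 times (seeded sub-streams,
every re-draw logged in the outcome's notes) before the
filter-skipping fallback applies, with all candidate scores recomputed
on the final split.  Calibration uses a single split; the 10-replicate
bootstrap is reserved for the chosen model, mirroring the two-stage
protocol.

## Mapping, areas, dynamics

AUC is the rank-based (Mann–Whitney) statistic of test presences vs the
background sample, ties counted half — invariant to monotone transforms
of the scores.  The replicate ensemble averages logistic rasters
cell-wise over converged replicates.  Multi-member (GCM-style) scenario
rasters are averaged cell-wise after a grid/mask identity check.
Jackknife importance reports regularized training gains for
with-only-this-variable and without-this-variable refits next to the
full-model gain.

Suitability classes use half-open, lower-inclusive intervals
[0,0.1) / [0.1,0.3) / [0.3,0.5) / [0.5,1]: strict inequalities on both
sides would leave boundary points unassigned, and exact threshold hits
are measure-zero.  Binarization of the suitable range is strict
(p > 0.1).  Cell areas are spherical quadrangles,
R²·Δλ·(sin φ_N − sin φ_S) with R = 6371.0088 km — across an 18–42°N
domain cell area varies by ~25%, so a flat-area constant would bias
both area tables and centroids.  Change matrices classify each valid
cell by its (current, future) binary pair; the conservation identities
(retained + lost = current suitable, retained + new = future suitable)
hold exactly by construction and are asserted in tests.

Range centroids are area-weighted means of suitable-cell centers over
the binary mask (not suitability-weighted — the centroid describes the
suitable-area matrix; a suitability-weighted variant would be a
different statistic).  Displacements use haversine distances (spherical
Earth; < 0.5% error vs ellipsoidal geodesics at these scales), initial
great-circle bearings, and local east/north components from an
equirectangular projection at the mean latitude, so cosine similarity
between migration vectors is computed in metrically meaningful
kilometres rather than raw degrees.

## Pipeline and formats

`run_pipeline` executes thin → screen → calibrate → replicate ensemble
→ scenario projection (replicate models projected and averaged, then
members averaged) → classes/areas → change matrices and centroid
tracks → cross-species similarity, per species, writing every artifact
under the output directory and a manifest with a config snapshot,
SHA-256 checksums of all outputs, and per-stage timings.  Re-running a
config reproduces every artifact bit-identically apart from timings.

Rasters are exchanged as ESRI ASCII grids — a textual format written at
`%.17g` precision so float64 arrays round-trip bit-exactly — with
header keys parsed case-insensitively; stacks are one `.asc` per layer
plus a YAML manifest of layer kinds and grid geometry.  Occurrences are
CSV (species, longitude, latitude, source); models serialize to JSON
(feature definitions, λ, β, scaling, entropy, metadata); displacement
vectors export as GeoJSON line features.

## Problem sizes

The packaged desk-scale conditions are: a 96 × 80 world (6336 land
cells), 200 presences, 2000-cell background, a 5 × 4 calibration grid,
10 bootstrap replicates, 500 partial-ROC iterations; the end-to-end
two-species pipeline demo runs on a 60 × 60 world with 150 presences
per species.  These sizes keep any single stage under a few seconds
while leaving every statistical contract testable.

## Known limitations

- AUC on presence-background data is bounded by niche breadth: for
  generalist species no model can score highly, so the packaged world
  uses a restricted species.
- AICc-based selection can prefer a feature combination without
  quadratic terms (e.g. LP) whose response surface cannot bend around a
  thermal optimum; at desk scale such a model can project a range shift
  in the wrong direction even when a quadratic model projects it
  correctly.  The pipeline reports what the protocol selects; the
  directional property is guaranteed only for models able to represent
  the unimodal response.
- The partial-ROC ratio estimator is mildly anti-conservative near the
  omission boundary (see above).
- Sampling bias, dispersal limitation, biotic interactions, terrain and
  soil are outside the generator and the model, as is any claim about
  real-world species; real-data headline numbers are not reproducible
  from synthetic worlds and are not targeted.
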