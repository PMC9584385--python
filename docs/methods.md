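# Methods

`fractalrad` computes three-dimensional fractal-geometry features from binary
tumour segmentation masks and runs the two-group statistical pipeline used in
radiogenomic studies that relate such features to a binary molecular marker
(here framed as TERT-promoter mutation status in grade 2 meningioma). This
note records the models, the numerical choices, and what the synthetic data
do and do not establish.

## Box counting

A mask is a binary 3D grid with isotropic voxel spacing (anisotropic inputs
must first pass through nearest-neighbour resampling, which preserves binary
values exactly; the default target is the smallest input spacing, so in-plane
resolution is never discarded). For a box size *r* (in voxels) the foreground
is cropped to its tight bounding box, zero-padded at the high end of each
axis to a multiple of *r*, and tiled by a fixed non-overlapping lattice
anchored at the bounding-box corner. `occupied_box_count` returns N(r), the
number of lattice boxes containing at least one foreground voxel, and the
per-box foreground masses. Padding can never create an occupied box, so the
statistics are invariant to zero-padding of the input.

The default size ladder is dyadic, r ∈ {2, 4, 8, 16, 32, 64, 128}. Sizes
exceeding the longest bounding-box axis resolve no structure and are skipped
(reported with a reason code); at least two usable sizes are required.

Design notes:

* **Fixed lattice, no gliding.** The non-overlapping corner-anchored lattice
  is the plainest box-counting construction. An optional
  `offset_averaging` flag averages counts and per-size CV² over the eight
  half-box lattice offsets as a variance-reduction device; it is off by
  default.
* **Orientation.** Axis permutations leave counts exactly unchanged. 90°
  rotations and flips move the padding to the other side of the bounding box
  and can change counts slightly; on tumour-like phantoms the fitted
  dimension moves by less than ≈0.1. Tests assert exact permutation
  invariance and bounded rotation sensitivity.

## Fractal dimension

FD is estimated from the count curve in two ways:

* `ols` (default): the least-squares slope of log N(r) against log(1/r) over
  all usable sizes, reported with the fit's R².
* `mean-local-slope`: the mean of log(N_j/N_{j+1}) / log(r_{j+1}/r_j) over
  consecutive size pairs.

Both agree exactly whenever N(r) is an exact power law: a solid cube of side
64 gives FD = 3 and a one-voxel slab FD = 2 to machine precision under
dyadic sizes dividing the side, and a level-4 Menger sponge under triadic
sizes {3, 9, 27} gives FD = log20/log3 ≈ 2.726833 because the counts are
exactly 20^k.

Finite-scale caveat: for solid objects the measured slope mixes a volume
term (exponent 3), a surface term, and — at sizes approaching the object
extent — lattice saturation where N(r) collapses to a handful of boxes.
Measured FD therefore depends on the ladder relative to the object size,
which is why tumour masks of a few centimetres yield FDs well below 3.

## Lacunarity

Lacunarity summarises the translational heterogeneity ("gappiness") of the
mask through the squared coefficient of variation of box masses, restricted
to boxes that intersect the mask. Two readings are implemented:

* `across-box-cv` (default): at each size with ≥2 occupied boxes,
  CV²(r) = (population SD / mean)² of the occupied-box masses; lacunarity is
  the mean of CV²(r) over contributing sizes. This is the occupied-box
  restriction of the classical gliding-box quantity Λ(r) − 1. Sizes with
  fewer than two occupied boxes are excluded and reported.
* `within-box-cv`: each occupied box with fill fraction p = m/r³ is treated
  as a Bernoulli field, for which CV² = (1 − p)/p in closed form; the
  per-size value is the mean over occupied boxes and lacunarity the mean
  over sizes.

All CV computations use the population (divide-by-n) variance, which makes
the documented hand cases exact: a solid cube gives 0 under both readings;
two boxes with masses {2, 6} give CV² = 0.25; a single voxel in an r = 2 box
gives (1 − 1/8)/(1/8) = 7.

Because the average is restricted to occupied boxes, uniform i.i.d. voxel
thinning *compresses* the mass distribution at small sizes (emptied boxes
leave the average) and can lower the statistic. Coherent gaps — the thing
lacunarity is meant to detect — raise it robustly when probed at box sizes
below the object diameter; the monotonicity experiment in the tests and the
acceptance script therefore carves spherical gaps into a digital ball and
measures at sizes {2, 4, 8}, where mean lacunarity rises strictly with the
deleted fraction (Spearman ρ = 1.0 across seed sets). Sizes comparable to
the object diameter are dominated by how the lattice happens to partition
the silhouette and are not informative about gaps.

Absolute lacunarity values depend on whether the grid is cropped to the
tumour bounding box (as here) or spans the whole image; only relative
comparisons within one convention are meaningful.

## Auxiliary shape features

* **Sphericity** π^{1/3}(6V)^{2/3}/S, equal to 1 for a perfect ball. V is
  the voxel-count volume in mm³. S is the area of the marching-cubes mesh of
  the 0.5 level set after smoothing the binary indicator with a 0.6-voxel
  Gaussian: a raw mesh of a binary grid inherits the voxel staircase and
  overestimates curved surface area by ≈8%, while the smoothed level set
  tracks the underlying surface (digital balls score ≥0.98, a cube lands
  within 2% of its closed form (π/6)^{1/3} ≈ 0.806). This surface-regularity
  measure is this package's own definition.
* **Maximum 3D diameter**: the largest Euclidean distance between foreground
  voxel centres in physical units, reported in cm. The farthest pair lies on
  the convex hull, so only hull vertices are compared (exact); degenerate
  point sets fall back to all-pairs.
* **Volume** in mm³ (voxel count × voxel volume).

## Synthetic phantoms

`make_primitive` builds exact digital cubes, slabs, lines and balls (voxel
centre within the radius). `make_menger_sponge` is the recursive 20-of-27
construction with known dimension log20/log3 and exact triadic counts.

`make_blob` is the tumour-like phantom. The border is the level set
|x − c| ≤ R(1 + a·n(x)) where n is multi-octave smooth noise (white noise at
coarse grids, cubic-spline upsampled, persistence 0.7, clipped at ±2.5 SD)
and a = 0.2·irregularity. Only wavelengths well below the object diameter
enter the field: coarse octaves merely deform the gross shape without
changing the measured slope. Spherical gaps of radius `gap_size_vox` are
carved at random interior sites until approximately `gap_fraction` of the
initial volume is removed, and the largest connected component is kept, so
the phantom is always a single component. Every generator is a pure function
of its arguments including the seed.

The irregularity knob is validated at the generator's default radius of
20 mm — at 1 mm voxels, a ≈4 cm tumour, the size scale of the intended
application — where roughening raises the measured dyadic-ladder FD in
10/10 seeds. Because the measured slope couples to where the ladder
saturates relative to the object extent, the direction of the effect is not
guaranteed for phantoms much smaller or larger than this; treat the knob as
calibrated at tumour scale rather than as a universal dimension dial.

## Synthetic cohort

`generate_cohort` draws a two-group table (wildtype/mutant) whose defaults
are the published group summaries of the motivating study population: 7/48
mutant prevalence; per-group Gaussian age, maximum diameter, FD
(1.74 ± 0.16 vs 1.88 ± 0.16) and lacunarity (5.51 ± 0.41 vs 6.01 ± 0.64);
Bernoulli clinical/imaging findings at the published per-group proportions;
optional pathology columns (mitoses, Ki-67) that never enter the imaging
model. FD draws are truncated to [1, 3] and lacunarity to (0, ∞) by
redrawing, which perturbs the moments negligibly at these parameter values.
The within-group FD–lacunarity correlation defaults to 0 because only
marginals are published; it is exposed as a knob since real features are
surely correlated, and downstream discrimination estimates inherit this
independence assumption.

The published two-feature model equation, logit p = −1.768 + 3.482·FD +
3.022·lacunarity, cannot be literal in raw feature units (it would assign
probability ≈1 to every subject), while its intercept alone reproduces the
cohort prevalence exactly (logistic(−1.768) = 0.146 = 7/48). It is therefore
interpreted as acting on mean-centred covariates. `simulate_logit_cohort`
uses it as simulation ground truth with centred Gaussian covariates of
SD 0.5 — enough information that a maximum-likelihood refit at n = 5000
pins each coefficient to a few percent while the event rate stays near the
source cohort's.

What the synthetic cohort does **not** emulate: feature correlations, any
link between a subject's mask geometry and their tabular feature values,
measurement error in segmentation, or site effects. Passing tests therefore
demonstrate correctness of the estimators and pipeline, not clinical
validity on real data.

## Statistical pipeline

* **Group comparisons.** Continuous variables: Shapiro–Wilk per group at
  α = 0.05 (a zero-variance group counts as non-normal); both normal →
  two-sided Welch t-test (unequal variances, the safer default when the
  published analysis does not specify pooling); otherwise two-sided
  Mann–Whitney U, exact when min(n) ≤ 20 without ties, normal approximation
  with tie correction otherwise. Categorical 2×2 tables: Fisher's exact when
  any expected count is below 5, chi-square with continuity correction
  otherwise.
* **Logistic modelling.** Maximum-likelihood logistic regression
  (Newton/IRLS via statsmodels) with Wald CIs on the odds-ratio scale.
  Complete separation (a term whose group ranges do not overlap) and
  quasi-complete separation (a binary term with an empty outcome cell, or
  touching ranges) are detected *before* fitting; separated terms are
  flagged and reported with no finite OR or CI, never with a spurious
  estimate. Firth-type penalisation is deliberately not applied — the
  pipeline mirrors the flag-and-report behaviour of the motivating analysis.
* **Backward elimination.** Candidates are terms with univariable Wald
  P < 0.05 (separated terms are excluded and recorded). From the full
  candidate model the term with the largest likelihood-ratio P is dropped
  while that P ≥ 0.05; the full elimination trace (term, LR P at removal) is
  retained. VIF is computed once on the candidate design matrix; terms with
  VIF ≥ 10 are reported, not auto-dropped (exact collinearity yields
  infinite VIF). An empty final model is a valid result.
* **ROC.** AUC by the rank method with midrank ties, identical to the
  Mann–Whitney U statistic divided by n₀n₁ (asserted to 1e-12 against a
  pairwise-comparison oracle). The 95% CI is a class-stratified percentile
  bootstrap (default 2000 replicates, seeded). The operating point maximises
  Youden's J over thresholds of the form "positive if score ≥ t"; ties on J
  resolve to the highest threshold. The published analysis names neither its
  CI method nor its operating-point rule; both choices here are documented
  defaults.
* **Agreement.** Cohen's kappa with marginal-product chance agreement (and a
  large-sample normal CI); undefined when both raters are constant.
  ICC(2,1) — two-way random effects, absolute agreement, single measure —
  via the standard two-way ANOVA decomposition; undefined at zero
  between-subject variance. "Two-way interrater correlation" is ambiguous
  between consistency and absolute agreement; the absolute-agreement variant
  is the stricter and is used here (a pure constant shift between raters is
  penalised).
* **Calibration.** Under a global null the univariable Wald screen rejects
  at the nominal 5% rate (1000 simulated cohorts of n = 200, 99% binomial
  band) — checked in the acceptance suite.

## Pipeline and reproducibility

`run_features` continues past per-subject failures and reports them (cohort
analyses tolerate missing subjects); it fails only when no mask is readable.
`run_analysis` writes a comparison table, the univariable/multivariable
model report with elimination trace and separation/VIF flags, and the ROC
summary, echoing every threshold and seed used. `run_simulate` writes
phantoms/cohorts with a sha256 manifest. All randomness (bootstrap, cohort
draws, phantom noise) sits behind explicit seeds; deterministic stages are
bit-reproducible and stochastic ones seed-reproducible.

Problem sizes used by the acceptance script — 64³ analytic bodies, a level-4
(81³) Menger sponge, 50 random oracle masks ≤32³, n = 5000 for coefficient
recovery, 2×20 000 subjects for the simulation-implied AUC, 2×100 000 for
moment recovery, 1000 null cohorts for screen calibration — are the
package's standard demonstration sizes; all complete in well under a minute
on one CPU except the calibration loop (a few seconds).

## Known limitations

* Absolute FD/lacunarity scales depend on the cropping and ladder
  conventions above; cross-study comparisons require identical conventions.
* The corner-anchored lattice makes counts only approximately invariant to
  flips; offset averaging reduces but does not remove this.
* Sphericity is a stand-in surface-regularity definition; other published
  "surface regularity" indices may differ by monotone transforms.
* The synthetic cohort's independence default understates the optimism of
  feature combinations relative to correlated real features.
* Separation handling reports divergence; it does not produce penalised
  estimates.
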