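# Methods

This package implements a gut–pelvis analysis pipeline: landmark-based
pelvimetry of the true pelvis, slice-summation CT volumetry of the gut,
observer-agreement ICC, and sex-specific allometric regression with a
relative-weights decomposition — together with a synthetic-data generator
that emulates the statistical structure of a 92-adult CT cohort (44 males,
48 females) so that every stage can be tested against known ground truth.

## Pelvimetry model

A specimen is an 11-landmark configuration in millimetres: left/right
ischial spines, left/right ischial tuberosities, sacral promontory, the
S4/S5 midpoint, the S5 apex, the dorsal superior and inferior pubic
symphysis points, and the two points of maximal iliopectineal width. Six
interlandmark distances give the anteroposterior (AP) and mediolateral (ML)
dimensions of the three obstetric planes:

| measure | landmarks | plane |
|---|---|---|
| IAP | promontory – dorsal sup. symphysis | inlet AP |
| IML | iliopectineal L – R | inlet ML |
| MAP | S4/S5 – dorsal inf. symphysis | midplane AP |
| MML | ischial spine L – R | midplane ML |
| OAP | S5 apex – dorsal inf. symphysis | outlet AP |
| OML | ischial tuberosity L – R | outlet ML |

Each plane's shape index is AP/ML. Two angles summarize the "spine
triangle" formed by the S5 apex and the two ischial spines: θ_a, the angle
at the S5 apex (smaller = more medially projecting spines), and θ_b, the
angle at the **left** ischial spine between the S5 line and the interspinous
line (larger = sacrum farther from the spines). Both are computed from the
three interlandmark distances by the law of cosines, mirroring the
distance-triangle construction; a dot-product vector computation exists only
as a test oracle, and the two agree to 1e-9 degrees on non-degenerate
configurations. Using the left spine as θ_b's vertex is a definition, not
an approximation: left/right asymmetry of a specimen is visible in θ_b and
is deliberately not symmetrized.

No anatomical axis frame is assumed — every statistic is invariant under
rigid rotation and translation, and under uniform scaling the lengths scale
while shapes and angles are unchanged. Triangles that are collinear within
a relative slack of 1e-6 raise a degenerate-geometry error; distance triples
violating the triangle inequality beyond that slack raise an
inconsistent-distances error. Degenerate values are never clamped or
returned.

## Volumetry model

Gut volume (GV) is the combined volume of the small and large intestines.
From a stack of binary masks with in-plane pixel spacing and slab thickness
(5 mm in the emulated acquisition), each slice contributes
(true-pixel count × row spacing × col spacing) × thickness, and the slab
volumes are summed (mm³, reported in cc). A slice's mask is treated as
constant through the full slab — no inter-slice interpolation and no
partial-volume correction.

Validation phantoms (cylinder, sphere, ellipsoid) are rasterized with a
center-of-pixel rule: a voxel is inside iff its center — including the
slice's mid-plane in z — is inside the solid, which is unbiased for convex
solids as the spacing shrinks. The summation error is first-order in the
grid spacing; note that on symmetric grids the rasterized area can tie
exactly at adjacent spacings (the r = 20 mm cylinder counts the same area at
2 mm and 1 mm), so refinement is non-increasing in error and strictly
improving overall, but not strictly monotone at every step. For the sphere
at 5 mm slabs the slab discretization, not the in-plane spacing, dominates
the error.

Masks are read from binary NIfTI volumes (spacing from the header, third
axis = slice direction) or multi-page TIFFs with a JSON sidecar carrying
`pixel_spacing_mm` and `slice_thickness_mm`. The pipeline is agnostic to
whether a mask includes the intestinal wall or lumen only; it consumes
whatever segmentation it is given.

## Observer reliability

Agreement on a measurement is the single-rater, absolute-agreement
intraclass correlation from the two-way ANOVA decomposition (ICC(A,1)):

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with subjects random and raters the fixed facet of the two-way mixed model.
The 95% interval uses the F-based method with Satterthwaite degrees of
freedom. The estimate is invariant to shifting or positively scaling all
ratings; zero between-subject variance raises an error rather than returning
0/0. Subjects with any missing rating are dropped listwise and the count
logged. Interpretation bands: ≥ 0.90 excellent, ≥ 0.75 good, ≥ 0.50
moderate (the conventional split; the package's upstream convention only
fixes the 0.75 and 0.90 boundaries), below that poor.

Because raters are fixed, the estimator converges (n → ∞, k fixed) to
σ²_s / (σ²_s + s²_r + σ²_e) where s²_r is the **realized** variance of the k
rater offsets; the convergence test therefore fixes offsets whose sample
variance equals the nominal σ²_r exactly, and observes agreement within 0.02
at n = 2000.

Landmarks without a sharply defined point — the ischial tuberosities, which
define OML — are "fuzzy": they are re-placed in replicate and the replicate
mean of each fuzzy-flagged field is carried into analysis. Replicates must
agree on all non-fuzzy fields within tolerance (they are repeat placements
of the fuzzy landmarks only). The outlet shape index is recomputed from the
averaged OML (ratio of means) rather than averaging per-replicate ratios,
since the averaged measurement is what enters analysis.

## Inference model

All variables — GV, body weight, and the 11 canal responses (six linear
dimensions, three shape indices, two angles) — are natural-log transformed.
The log base only rescales coefficients; p-values and R² are unaffected.
Angles are logged like everything else by default; a raw-angle analysis is a
one-line change (skip them in the transform) if a user objects that angles
are not ratio-scale.

Per sex and response, ordinary least squares with intercept:

* males: `log(canal) ~ log(GV) * log(weight)` — weight interacts, because
  male GV scales on weight with negative allometry;
* females: `log(canal) ~ log(GV) + log(weight)` — additive, because female
  GV is independent of weight. A nested-model F-test
  (`compare_interaction`) verifies that adding the interaction does not
  improve female fits.

The headline "R²" of a report row is the **adjusted** R² (it can be
negative for uninformative models, and negative entries are legitimate
report content); the raw R² is reported alongside and is the quantity the
relative-weights decomposition partitions. Coefficient p-values are
marginal two-sided t-tests from the fitted model; the model p-value is the
overall F-test. Significance flags: `**` for p ≤ 0.01 (the conservative
primary threshold), `*` for 0.01 < p ≤ 0.05. No multiple-testing correction
is applied across the 11 responses — the tightened α plays that role — and
the number of tests is logged.

Relative weights (Johnson's ε) decompose the raw R² into non-negative
per-predictor shares: with predictor correlation matrix
R_xx = V diag(λ) Vᵀ and its symmetric square root Λ = V diag(√λ) Vᵀ,
β = Λ⁻¹ r_xy and ε = (Λ∘Λ)(β∘β). Σε equals the OLS raw R² (to 1e-10 in
tests), and under in-sample orthogonality ε_k reduces to the squared
correlation of predictor k with the response. Weights are computed on the
two main predictors (GV, weight) in **both** sexes — the male interaction
term is excluded — so every model yields exactly two percentages summing to
100. Reporting follows that convention; the relative-importance table lists
models significant at α = 0.01.

Body-mass grouping for the stratified scatter plots uses the per-sex sample
mean ± 1 SD (ddof = 1): strictly below mean − SD is "low", strictly above
mean + SD is "high", boundaries inclusive to "mid".

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the emulated
study conditions:

* **Cohort size** 44 males / 48 females.
* **Body weight** truncated-normal (> 0): 80.43 ± 19.27 kg (M),
  67.17 ± 13.15 kg (F). **Stature** 1.77 ± 0.07 m (M), 1.64 ± 0.07 m (F).
* **Gut volume**: females truncated-normal 4192.13 ± 912.44 cc,
  independent of weight; males log GV = a + b·log W + N(0, 0.148) with
  negative allometry b = 0.8 (the emulated scaling is "slightly below
  isometry"; the exponent is config-exposed) and the intercept a solved
  numerically so that E[GV] = 5384 cc given the weight distribution. The
  0.148 log-noise reproduces the male GV coefficient of variation implied by
  5384 ± 1320.86 cc.
* **Canal measures**: the eight base measures (six linear + two angles) are
  generated in log space around a template (IAP 110, IML 125, MAP 115,
  MML 100, OAP 95, OML 115 mm; θ_a 72°, θ_b 54° — realistic adult
  magnitudes carrying no claim about any real sample) plus linear effects of
  log GV and log weight (and their product in males) and Gaussian residual.
  Shape indices follow as AP/ML ratios, so a shape's implied effect is the
  difference of its parents' (`true_effects` exposes the implied truth for
  any response). Female effect defaults take the additive-model
  coefficients of the emulated study verbatim (e.g. θ_a: −0.11 on log GV,
  −0.099 on log weight); male defaults are modest ML-widening effects with a
  small positive interaction on IML and MML, because the published male
  interaction-model coefficients live on a collinear raw-product scale and
  are not usable as generative magnitudes. Residual log-SDs are 0.12 for
  linear dimensions — chosen so significant simulated models land at
  R² ≈ 0.1–0.3, the band real canal~GV+weight fits occupy, rather than the
  0.7+ a 0.05 residual would give — and 0.05 for the angles, which keeps
  θ_a + θ_b < 180° effectively certain under multiplicative noise.
* **Landmarks**: a constructive template reproduces a row's eight base
  measures exactly before noise (spine triangle solved from MML, θ_a, θ_b by
  the law of sines; remaining landmarks placed along fixed unit directions
  at the prescribed distances). Observation error = per-observer systematic
  per-landmark bias (SD 0.5 mm, fixed across specimens) + per-observer
  random jitter (SD 1 mm) shared across replicates + per-replicate jitter on
  the fuzzy tuberosities only (SD 5 mm). This makes OML the least reliable
  measure, reproduces the replicate-averaging contract by construction, and
  with zero noise round-trips exactly through the measurement stage.
* **Masks**: a gut-volume target is rasterized as the set of voxels nearest
  the grid center at (1 mm, 1 mm, 5 mm) geometry, filled to the exact target
  voxel count — accurate to half a voxel (0.0025 cc), so slice summation
  recovers the generating GV essentially exactly.

Everything is deterministic given the config seed; per-observer bias streams
are derived from dedicated seed sequences so landmark sets are reproducible
independent of iteration order.

### What the generator does and does not emulate

It emulates the *statistical* structure: per-sex marginals, the sex-specific
GV–weight dependence, linear log-scale effects on canal measures, fuzzy
landmark noise, and the slab geometry. It does not emulate anatomy beyond
measurement magnitudes (no real pelvis shape variation, no correlated
residuals between canal measures, no intestinal morphology, no segmentation
error, no age structure). Passing tests therefore demonstrate that the
pipeline's estimators are correct and calibrated under the assumed model —
not that the assumed model captures every feature of real CT cohorts.

## Numerical choices

* Triangle degeneracy slack: 1e-6 relative to the largest side.
* Predictor correlation matrices with a minimum eigenvalue ≤ 1e-10 raise a
  collinearity error (no pseudo-inverse fallback).
* Truncated-normal sampling by rejection (the means sit 3–5 SD above zero,
  so rejection is essentially free); truncated moments for the male GV
  intercept and the centering constants by numerical integration, cached.
* The interaction comparison refuses to return a p-value when the
  interaction column adds no rank to the design.
* ICC with MS_E = MS_C = 0 (perfect agreement) reports a degenerate [1, 1]
  interval rather than evaluating the F formulas at 0/0.

## Problem sizes

Test and acceptance simulations run at the design's cohort sizes (44/48)
where calibration is asserted: 500 cohorts for CI coverage (nominal 95%,
asserted ≥ 93%), 200–250 null cohorts × 22 models for the p ≤ 0.01 flag rate
(asserted ≈ 0.01 within Monte-Carlo error), 2000 simulations for the
interaction type-I rate (0.05 ± 0.02), 500 for its power check, and 500
end-to-end landmark→regression recovery runs. Generator moment checks use
n = 10000–20000 per sex. The full suite runs in a few minutes on one CPU.

## Known limitations

* The pipeline consumes landmarks and masks; digitization, surface-model
  extraction, and intestine segmentation from grayscale CT are out of scope.
* θ_b is defined at the left spine only; bilateral asymmetry enters the
  statistic by design and no right-vertex or averaged variant is computed.
* Relative weights are an approximate decomposition; with the male
  interaction term excluded, the two percentages describe the main-effect
  predictors only.
* The regression treats measured GV and weight as error-free predictors; no
  measurement-error or mixed-effects modelling.
* Canal responses are generated with independent residuals, so the observed
  correlation between report rows understates what anatomically coupled
  measures would show.
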