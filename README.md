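# pelvimetrics

Does the size of the gut leave a signature on the bony pelvic canal? The
human true pelvis must simultaneously support the abdominopelvic viscera —
dominated by the volume of the small and large intestines ("gut volume",
GV) — anchor the pelvic floor at the ischial spines, and, in females, leave
room for childbirth. `pelvimetrics` is a tested pipeline for studying that
trade-off in CT cohorts: it measures the pelvic canal from 3D landmarks,
measures gut volume from segmentation masks, quantifies observer agreement,
and relates canal geometry to gut size and body weight with sex-specific
allometric regression.

It is aimed at biological anthropologists and clinical researchers working
with landmark and volumetric data, and ships a synthetic cohort generator
with fully known ground truth, so every estimator in the pipeline has a
parameter-recovery test surface.

## What it computes

**Pelvimetry.** From 11 canal landmarks: AP and ML diameters of the inlet
(IAP, IML), midplane (MAP, MML) and outlet (OAP, OML); shape indices AP/ML
per plane; and two angles of the S5-apex/ischial-spine triangle computed
from interlandmark distances by the law of cosines — θ_a at the S5 apex
(smaller = more medially projecting spines) and θ_b at the left spine
(larger = sacrum farther from the spines).

**Volumetry.** Slice-summation gut volume: per-slice segmented area × slab
thickness (5 mm design), summed over the stack; validated against analytic
cylinder/sphere/ellipsoid phantoms rasterized with a center-of-pixel rule.

**Reliability.** Single-rater absolute-agreement ICC from the two-way
ANOVA decomposition,

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),

with F-based 95% CIs, plus the fuzzy-landmark rule: outlet-ML replicates are
averaged before analysis.

**Inference.** After natural-log transform, per sex and canal response:
`log(canal) ~ log(GV) * log(weight)` in males (GV scales on weight with
negative allometry) and `log(canal) ~ log(GV) + log(weight)` in females (GV
and weight independent), with adjusted R² as the headline, `**`/`*` flags at
α = 0.01/0.05, a nested-model F-test for the female interaction, and a
Johnson relative-weights decomposition of each model's raw R² into the
percentage shares of GV and body weight.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort at the design's sample sizes (44 M / 48 F, seed 20211):

```bash
python analysis/01_simulate_cohort.py      # cohort + landmark tables
python analysis/02_measure_canal.py        # pelvimetry + fuzzy averaging
python analysis/03_gut_volumetry.py        # phantom + mask validation
python analysis/04_observer_reliability.py # ICC per measurement
python analysis/05_allometric_regression.py# regressions + relative weights
```

Step 04 prints, per canal measure, the two-observer ICC — the fuzzy
ischial-tuberosity landmarks make OML the least reliable measure, exactly
the pattern that motivates replicate averaging:

```
measurement_name   icc  ci_low  ci_high  n  k agreement
             IAP 0.982   0.970    0.989 92  2 excellent
             OML 0.863   0.797    0.908 92  2      good
         theta_a 0.950   0.926    0.967 92  2 excellent
```

Step 05 prints the per-sex regression table and the relative-importance
breakdown of the significant models, e.g. (abridged):

```
   sex                    label  beta_gv   p_gv flag_gv  beta_weight      r2  model_p flag_model
female Ischial Spine Projection  -0.1402 0.0000      **      -0.0967  0.4061   0.0000         **
female              S5 Position   0.2398 0.0000      **       0.1574  0.6708   0.0000         **

   sex response                    label  rw_gv_pct  rw_weight_pct
female  theta_a Ischial Spine Projection       83.6           16.4
female  theta_b              S5 Position       84.9           15.1
```

Read: in the simulated females, a one-percent increase in gut volume is
associated with a 0.14% *decrease* in θ_a (more medially projecting spines)
and a 0.24% increase in θ_b (sacrum farther from the spines), and gut volume
— not body weight — accounts for most of each model's explained variance.
Both effects recover the generator's configured truth (−0.11 and 0.26 up to
sampling error), which is the point: the estimates are calibrated, and the
same pipeline runs unchanged on real landmark/mask data.

The same pipeline is available as a CLI:

```bash
pelvimetrics run --simulate --seed 7 --n-male 44 --n-female 48 --out results/run7
pelvimetrics measure --landmarks landmarks.csv --out canal.csv
pelvimetrics icc --measurements ratings.csv --out icc.csv
pelvimetrics regress --cohort cohort.csv --out results/
```

`run` writes a manifest (config hash, seed, input/output checksums) and is
byte-identical under re-execution with the same seed. Exit codes: 2 schema
error, 3 degenerate geometry, 4 statistical failure.

## Layout

```
src/pelvimetrics/   morphometry, volumetry, reliability, inference,
                    synthetic (generator), cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite incl. acceptance-level checks
docs/methods.md     model assumptions, parameter choices, limitations
```
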