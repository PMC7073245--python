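# Methods

This note documents the models, parameter choices and numerical decisions
behind `histoprog`, and what the synthetic-data tests do and do not
demonstrate about real slide cohorts.

## Stain model and estimation

Transmitted intensity is converted to optical density per channel as
`OD_c = -log10(max(I_c, 1) / I0)` with background intensity `I0 = 255`
(8-bit input). Log base 10 follows the classical deconvolution literature;
any base change rescales concentrations and the per-stain maxima together
and leaves rendered output unchanged. Intensities are floored at 1 so
saturated-dark pixels stay finite.

The 3×2 stain matrix is estimated per image by plane fitting: tissue pixels
(mean OD > `od_min = 0.15`) are projected onto their top-2 right-singular
plane, and the 1st/99th-percentile extreme angles of the projected cloud
(`angle_percentile = 1`) are taken as the stain directions. Extreme-angle
vectors are clipped to the non-negative orthant and unit-normalized;
hematoxylin is the column with the larger red-channel component (hematoxylin
absorbs strongly in red, eosin barely), which fixes the column order
deterministically. Failure modes are explicit: fewer than 100 tissue pixels
raises an insufficient-tissue error; a top-2 singular-value ratio above 50
(effectively one stain) raises a degenerate-stain error.

Deconvolution solves a per-pixel 2-variable non-negative least squares
problem in closed form (interior solution of the 2×2 normal equations, else
the better of the two boundary candidates); tests verify agreement with a
brute-force NNLS oracle per pixel.

Normalization rescales concentrations by `reference.max_density /
source.max_density` per stain — with `max_density` the 99th percentile of
tissue-pixel concentrations, robust to outliers — and re-renders through the
reference matrix. The default reference uses the classical published H&E OD
vectors (H = (0.65, 0.70, 0.29), E = (0.07, 0.99, 0.11), normalized) with
conventional concentration maxima (1.97, 1.03).

Color augmentation multiplies each stain's concentration channel by an
independent `Uniform[multiplier_low, multiplier_high]` draw and re-renders.
The default range is [0.95, 1.05]: a mild perturbation that preserves class
structure; the bounds are configuration knobs because no canonical value
exists. The default count is 50 augmentations per image.

## Patch sampling and aggregation

Crops (default 20 per augmented image, sizes 256² or 512²; other sizes only
behind an explicit flag) are drawn uniformly with replacement over valid
0-based, half-open origins. A tissue filter (default `min_tissue_fraction =
0.5` at mean-OD threshold 0.15) rejects background-dominated crops with up
to 100 redraws each, after which the best-seen crop is kept and a warning
emitted; setting the fraction to 0 disables filtering entirely for a
literally-uniform sampler. Coverage accounting is nominal (overlap ignored):
`100·count·size²/(W·H)` — 41.6% for 20×512² and 10.4% for 20×256² on the
median 5601×2249.5 slide raster.

Per-crop vectors are aggregated with the elementwise median over all crops
of all augmentations, and per-image vectors to per-subject vectors the same
way. The median is permutation-invariant and monotone, both covered by
property tests.

## Feature extractors

Pooled convolutional backbones produce one scalar per channel (global
average pooling), so their output dimensionalities are forced by channel
arithmetic: 128+256+512+512 = 1408 for the four late VGG16 stages,
320+768+768+192 = 2048 for Inception V3's final mixed block, 512×4 = 2048
for ResNet50's final bottleneck. These constants are exposed without
instantiating a network; actual pretrained extraction is an optional plug-in
requiring torch/torchvision. The default extractor is deterministic and
weights-free: density-normalized per-channel intensity histograms (3×64
bins) through a fixed Gaussian random projection seeded by the extractor
name. It is crop-size independent and makes every downstream stage fully
reproducible offline.

## Classification and embedding

Visualization reduces features with exact-SVD PCA to 10 components followed
by seeded Barnes–Hut t-SNE (perplexity 15) to 2-D. Classification uses a
linear SVM (C = 1) under stratified 6-fold cross-validation; features are
standardized with train-fold statistics before the margin fit — standard
practice for stable linear-model behavior across heterogeneous activation
scales. Per-fold held-out ROC AUCs are reported with their mean; average
precision is computed from pooled out-of-fold decision scores (the simplest
construction yielding a single PR summary per model).

## Survival modelling

Univariate screening uses the score (log-rank) test of a single Cox
covariate at β = 0 with Efron tie handling — no iteration is needed at the
null, so it vectorizes over thousands of features; a null simulation checks
the p-values are uniform and the selection rate at 0.05 is 3–7%. Full
univariate fits (coefficient, hazard ratio) use Newton iteration with Efron
ties via lifelines. Near-constant features (variance < 1e−12) are excluded
from screening with a warning. Subjects missing an endpoint are dropped for
that endpoint only.

The multivariate model fits an elastic-net penalized Cox likelihood
(mixing α = 0.5) over a 100-value log-spaced λ path by coordinate descent
(scikit-survival's glmnet-style solver), with features standardized
internally. λ is selected by minimum mean 10-fold cross-validated
partial-likelihood deviance (−2× the Breslow partial log-likelihood of the
held-out fold at the fold model's predictors); the minimum-deviance rule is
the common default where no one-standard-error convention is specified. The
reported C-index is Harrell's C (ties in risk count 0.5) on out-of-fold
linear predictors, with fold-wise values retained for mean ± sd summaries;
the model-level log-rank p splits subjects at the median out-of-fold risk
score — an explicit construction chosen so a continuous-risk model yields a
reproducible two-group test.

Kaplan–Meier curves use the product-limit estimator with the two-sided
(multivariate) log-rank test across groups.

## Subgroup discovery

K-means (k-means++ initialization, `n_init = 10`, fixed seed) is scanned
over K = 2–12 on standardized, doubly survival-significant features. K is
chosen by maximum mean silhouette; the Davies–Bouldin index (lower is
better) breaks ties, then smaller K. When the planted separation spans all
feature dimensions both metrics agree at the planted K in ≥95% of seeded
replicates; when the separation lives on a sparse subspace amid many noise
dimensions, Davies–Bouldin keeps decreasing with K while silhouette still
identifies the planted K — one reason silhouette owns the decision.
Subgroups are renumbered by increasing area under the KM curve, so the
highest-numbered group always has the best prognosis ("group 2" for K = 2).
Subgroup survival contrast fits a Cox model on group indicators; its linear
predictor serves as the risk score for the C-index.

## Pathway correlation and differential activity

Pathway-entity ids follow the Firehose PARADIGM dialect
`<pathwayIndex>_<concept>`; parsing splits at the first underscore and
rejects non-integer prefixes and duplicate ids by name. Pearson correlations
between every feature and every entity are computed on the exact sample-id
intersection (≥3 shared samples required); two-sided p-values come from the
t transform, and Benjamini–Hochberg adjustment pools globally over all
feature×entity pairs within a configuration — the conservative reading where
no pooling scope is canonical. Constant columns get r = 0, p = 1.

Differential entity activity between two subgroups uses a moderated
t-statistic with empirical-Bayes variance shrinkage, reimplemented rather
than delegated: per-entity pooled variances are shrunk toward a prior whose
scale `s0²` and degrees of freedom `d0` are estimated from all entities by
moment matching on log-variances (mean and variance of `log s²` under the
scaled-F marginal, with a Newton trigamma inversion). The posterior variance
is `(d0·s0² + d·s²)/(d0 + d)` and the statistic is referred to a t
distribution with `d + d0` degrees of freedom (normal when `d0 = ∞`, i.e.
when observed variances are no more dispersed than sampling noise). A test
verifies agreement with the reference R implementation to 1e−8, and
`prior_df = 0` recovers the ordinary pooled t. A Welch t is available as a
configuration fallback. Differential significance uses BH ≤ 0.1.

## Synthetic data

`simulate_he_image` renders two-stain Beer–Lambert images: eosin-only
cytoplasm (concentration `U(0.2, 1.0)`), hematoxylin-rich nucleus disks
(`U(0.6, 1.2)`, eosin suppressed ×0.05 inside nuclei), Gaussian
concentration noise (sd 0.02), and a pure-white background strip
(`background_fraction` of columns). Near-pure pixels of each stain anchor
the percentile-angle estimator, which recovers the ground-truth vectors
within 2°. The generator mimics only two-stain absorption structure — not
real tissue morphology, scanner artifacts, pen marks or focal blur — so
passing stain tests demonstrates correctness of the deconvolution machinery,
not robustness to real-slide pathology.

`simulate_cohort` draws standard-normal features for `n_tumor + n_normal`
samples (defaults 120/30, preserving the ~4:1 tumor:normal ratio of the
motivating cohort at desk scale). The tumor/normal class shift (default 3
sd) and each planted cluster shift (default 3 sd, K = 2) act on disjoint
random feature subspaces of size ~p/10. Survival times are exponential-
baseline Cox draws (`baseline_hazard = 1/365` per day) with linear predictor
`X·β`; censoring is independent `Uniform(0, c)` with `c` solved by bisection
on the realized draws to hit the target fraction exactly in expectation
(default 0.3), keeping censoring non-informative and deterministic given the
seed. Disease-free survival shares the OS coefficient support with damped
(0.8×) and jittered magnitudes — prognostic features plausibly matter for
both endpoints, and a non-empty doubly-significant set is what the subgroup
stage consumes. Gaussian features with mean-shift structure do not reproduce
the heavy tails, feature correlations or batch effects of real CNN
activations; recovery tests therefore certify the estimators, not their
behavior under real-data misspecification.

`simulate_ipl` builds coupled entities as `ρ·z + sqrt(1−ρ²)·ε` on the
standardized feature, hitting the target correlation in expectation, with
independent-noise entities elsewhere and ids synthesized in the
`<index>_<name>` dialect.

## Problem sizes and determinism

The test suite and the analysis drivers run at deliberately modest sizes —
cohorts of 120–500 subjects, 30–500 features, 18 rendered 96–128 px images
with 2–5 augmentations and 3–8 crops — chosen as the smallest scales at
which every calibration and recovery property is stable across seeds; the
production defaults (50 augmentations, 20 crops, 256²/512², K = 2–12)
remain the configured values throughout. All randomness flows through
explicit integer seeds; the pipeline derives per-stage seeds as
`sha256(master_seed, stage)`, so stages are independently reproducible and a
rerun with identical inputs is bit-identical for deterministic extractors.

## Known limitations

Pretrained CNN extraction requires optional heavy dependencies and slide
archives that the package does not ship; the weights-free extractor stands
in for pipeline exercise but produces features with no claim to biological
content. No proportional-hazards diagnostics, time-dependent covariates or
competing risks. The coverage statistic ignores crop overlap. The pyramid
slide reader is out of scope; inputs are plain PNG/TIFF exports.
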