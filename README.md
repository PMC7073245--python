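# histoprog

Histopathology slides carry prognostic signal that standard clinical tables
miss. `histoprog` is a tested, end-to-end reimplementation of a transfer-
learning prognostics workflow for H&E-stained whole-slide cohorts (developed
against the TCGA-LIHC hepatocellular-carcinoma setting): stain-color
normalization and augmentation, patch-level feature extraction with median
aggregation, tumor/normal classification, Cox survival modelling, unsupervised
subgroup discovery, and FDR-controlled correlation of image features with
molecular pathway activities. Every stage can be exercised on synthetic data
with known ground truth, so the whole pipeline is testable on a laptop without
any slide downloads.

## The models at the core

**Stain deconvolution.** Per RGB channel, optical density `OD = -log10(I/I0)`
is additive over the two dyes (Beer–Lambert), so each pixel satisfies
`OD ≈ M c` with `M` a 3×2 unit-column stain matrix and `c ≥ 0` the
hematoxylin/eosin concentrations. `M` is estimated per image by the classic
plane-fitting procedure (SVD of tissue-pixel OD, extreme 1st/99th-percentile
angles in the projection plane); normalization rescales `c` by the ratio of
robust (99th-percentile) concentration maxima and re-renders through a common
reference matrix; color augmentation multiplies each concentration channel by
`Uniform[0.95, 1.05]` draws and re-renders.

**Features.** Each normalized image yields 50 augmentations × 20 random crops
(256² or 512²); a pluggable extractor maps each crop to a vector and the
elementwise **median** over all crops of all augmentations represents the
image (and the median over a subject's images represents the subject).
Pretrained convolutional backends pool one scalar per channel, so their
dimensionalities are architecture facts: VGG16's four late stages give
128+256+512+512 = 1408 features, Inception V3 and ResNet50 give 2048. A
deterministic, weights-free histogram–random-projection extractor is
first-class for offline runs.

**Prognosis.** Each feature is screened univariately with the Cox
proportional-hazards score (log-rank) test (Efron ties, `p ≤ 0.05`); the
multivariate model is an elastic-net Cox fit (`α = 0.5`, 100-value λ path,
λ chosen by minimum 10-fold cross-validated partial-likelihood deviance),
evaluated by Harrell's C on out-of-fold linear predictors and a log-rank test
at the median out-of-fold risk. Subgroups come from K-means (K = 2–12,
silhouette with Davies–Bouldin tie-break) on the features significant for
both overall and disease-free survival. Image features are related to
PARADIGM Integrated Pathway Levels (`<pathwayIndex>_<concept>` entities) by
Pearson correlation with global Benjamini–Hochberg control at 0.05, and
entities are tested between subgroups with an empirical-Bayes moderated
t-statistic (BH ≤ 0.1).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(about a minute total):

```bash
python analysis/01_simulate.py           # images + cohort + IPL ground truth
python analysis/02_stain_and_features.py # normalize/augment/crop/extract
python analysis/03_classification.py
python analysis/04_survival.py
python analysis/05_subgroups.py
python analysis/06_pathways.py
```

which prints (abridged):

```
image_route: mean AUC 1.000, AP 1.000
OS: 9/60 features selected (15.0%)
DFS: 8/60 features selected (13.3%)
significant for both OS and DFS: 6 (planted OS signal recovered: 5/5)
elastic net OS: lambda 0.1553, C-index 0.857, log-rank p 1.34e-38,
  10 nonzero coefficients (planted recovered: 5/5)
chosen K = 2 (silhouette 0.601, Davies-Bouldin 0.599)
OS: log-rank p 8.30e-38, C-index 0.785 (group 2 = better prognosis)
14 significant feature-entity pairs; 100.0% of features have at least one
differential activity between OS subgroups: 2 entities at BH <= 0.1
```

Reading: the rendered tumor/normal slides separate perfectly (AUC 1.0); the
univariate screen selects roughly the planted prognostic features plus the
expected ~5% false positives; the elastic net recovers all five planted
coefficients with an out-of-fold C-index of 0.86; silhouette and
Davies–Bouldin agree on the planted K = 2 subgroups, which differ strongly in
survival; and the correlation/differential stages find exactly the entities
that were coupled to image features by construction.

A console script exposes the same stages (`histoprog simulate|normalize|
augment|run-all ...`).

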