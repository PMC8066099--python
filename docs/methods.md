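# Methods

## Scope and data model

The package reimplements a pretreatment-MRI radiomics protocol for binary
outcome prediction (pCR vs residual disease after neoadjuvant
chemoradiotherapy in locally advanced cervical cancer). Its unit of data is
`VolumeWithMask`: a 3D intensity array indexed (row, col, slice) with
per-axis voxel spacing in mm and an aligned binary ROI. The positive class
is pCR throughout; microscopic and macroscopic residual disease both map to
the negative class, and every report records this encoding.

## Preprocessing and filter banks

**Planar resampling.** Volumes are resampled to a common in-plane spacing
(default 0.548 mm) slice by slice; the slice axis is never resampled, since
slice thickness varies across acquisition protocols and resampling it would
manufacture data. Intensities are linearly interpolated (monotone, exact on
constants); masks are linearly interpolated and re-binarised at 0.5. The
interpolation scheme and the 2D (rather than 3D) treatment are package
choices — the protocol constants fix only the target in-plane spacing.

**LoG bank.** The Laplacian-of-Gaussian response is computed per axial
slice at σ = 0, 0.35, …, 4.2 mm (13 widths), with σ converted to pixels
through the in-plane spacing. σ = 0 is defined as "no filtering" (the raw
image). The discrete kernel is the truncated sampled LoG *shifted to sum
exactly to zero*: a truncated sampled kernel has a small DC component
(relative response to a constant image of order 1e-4 at σ ≈ 1 px), and
zero-normalising it restores the defining property that constant regions
produce zero response. Filtering is 2D for the same reason resampling is.

**IB filter.** ROI intensities are linearly mapped so the 1st ROI
percentile → 0 and the 99th → 1, clipped to [0, 1]; a constant ROI raises a
degenerate-normalisation error. Subpopulations are all voxels with
normalised intensity in the *closed* interval [l/100, u/100] for each of
the 55 level pairs l < u drawn from {0, 10, …, 100}. Closed intervals mean
boundary voxels belong to both adjacent bands — a deterministic, documented
convention; the union of the ten adjacent 10 %-wide bands is exactly the
ROI.

## Feature families

First-order features (18: moments, quantiles, dispersion, histogram
entropy/uniformity, energy, RMS) are computed on every LoG image over the
whole ROI. Kurtosis uses the **Pearson** convention (normal ⇒ 3); variance
and skewness use the population (biased) convention; entropy and uniformity
use a 32-fixed-bin histogram over the observed range.

GLCM, fractal and morphology features are computed on every IB
subpopulation:

* **GLCM** — grey levels are discretised to 32 equal-width bins over the
  masked intensity range; co-occurrences are accumulated per slice over the
  four planar directions at distance 1, pairs counted only when both voxels
  belong to the mask, summed over slices and directions, symmetrised and
  normalised. Features: contrast, correlation, energy, homogeneity,
  entropy, cluster shade, cluster prominence. Bin count, distance and
  direction handling are exposed in `BankConfig`; the defaults are common
  IBSI-compatible choices. Degenerate correlation (zero marginal variance)
  is reported as 0.
* **Fractal** — per-slice box-counting dimension: least-squares slope of
  log N(ε) against log (1/ε) over dyadic box sizes spanning the slice
  bounding box; a single pixel has dimension 0 by convention. Reported as
  the mean, SD and maximum over non-empty slices (the "maximum fractal
  dimension" of the protocol).
* **Morphology** — voxel volume, exposed-voxel-face surface area,
  sphericity derived from those two, maximum in-plane diameter between
  pixel centres (convex-hull accelerated), and the number of 8-connected
  planar components summed over slices. Connectivity is a package choice;
  the protocol never defines it.

Subpopulations smaller than 8 voxels (and empty ones) yield NaN sentinels
for GLCM/fractal features rather than meaningless statistics; extraction
never aborts. The default bank census is 13·18 + 55·(7+3+5) = 1059 and is
logged, not asserted against any external count: the 1889-feature census of
the original study is not reconstructible from its description, so the bank
is configuration-defined with the same structural skeleton.

Downstream, features missing in more than 20 % of cases are dropped and the
remaining missing values are median-imputed (`prepare_table`); constant
columns are dropped too. These thresholds are recorded in the run report.

## Feature selection

Eight stratified folds (stratification by outcome prevents folds without
responders at ~40 % prevalence; the protocol says only "randomly divided").
For each leave-one-fold-out subset, each feature is tested two-sided:
Welch t-test when both classes pass Shapiro–Wilk at α = 0.05, otherwise
Wilcoxon–Mann–Whitney (exact for small tie-free samples, tie-corrected
normal approximation otherwise). The normality gate additionally requires
at least 8 observations per class — below that Shapiro–Wilk has essentially
no power and would wave tiny samples through to the t-test. Constant
features score p = 1.

A feature significant (p < 0.05) in ≥ 5 of the 8 subsets enters the stable
set. Pruning is greedy: candidates ordered by ascending median p across the
8 subsets (ties: more votes, then lexicographic id), accepted iff
|Pearson r| < 0.6 against every feature already accepted. Absolute r is
used because an anti-correlated duplicate is just as redundant; the
survivor rule (smallest median p first) is a package choice — the protocol
specifies neither.

Selection runs **once on the full merged cohort, before model
cross-validation**, reproducing the original workflow. The held-out CV
folds therefore participate in feature selection, and every downstream CV
AUC inherits an optimistic bias. This is documented in the selection report
and quantified below rather than silently corrected.

## Model selection and evaluation

Fifteen classifier configurations are compared (`modeling.ROSTER`). Each is
the nearest scikit-learn equivalent of a standard method family: entropy
decision tree (C5TREE), boosted depth-3 trees (DT), regularised QDA (HDDA),
distance-weighted 7-NN (KNN), unpenalised logistic regression (LOGREG),
Gaussian naive Bayes (NB), one-hidden-layer MLP (NN), shrunken nearest
centroids with sigmoid calibration (PAM — centroid models emit no native
probabilities, so a monotone calibration fitted on training folds supplies
them), ridge-shrinkage LDA with fixed 0.5 shrinkage (PDA) and with
Ledoit–Wolf automatic shrinkage (SDA), a PLS-regression classifier with
clipped scores (PLS), degree-3 polynomial SVM with Platt probabilities
(SVM), and three random forests. Scale-sensitive learners are standardised
inside their pipeline. Hyperparameter defaults per key live in
`make_classifier` and are deliberately ordinary.

`RF_DEF` uses ntree = 500 and mtry = ⌊√p⌋ for p selected features. `RF_GRID`
and `RF_RAND` tune mtry over up to 10 candidates (an even grid over 1..p,
or a seeded random draw), scoring each candidate by the **out-of-bag AUC**
of a 500-tree forest fitted on the training folds only. OOB scoring is the
canonical tuning practice in the R random-forest ecosystem this roster
mirrors, and it needs one forest per candidate where an inner
cross-validation would need three or more.

Each classifier is evaluated by 3 repeats of stratified 8-fold CV with a
fresh randomised split per repeat (24 held-out AUCs); these splits are
drawn independently of the selection folds. AUC is the trapezoidal area
under the ROC built over unique score thresholds with the
"score ≥ threshold ⇒ positive" rule; it equals the Mann–Whitney pair count
with the ½-tie convention (property-tested). A classifier failure on a fold
is recorded as NaN and excluded from the mean, never imputed. Ranking is by
mean AUC, ties by smaller sample SD (n − 1 over the 24 values), then roster
order. The winner is refitted on the whole cohort; the Youden-optimal
threshold (J = sensitivity + specificity − 1, ties toward the higher, more
specific threshold) is reported with sensitivity, specificity and accuracy.

## Synthetic cohorts

`PhantomSpec`/`generate_cohort` emulate the study cohort with texture
phantoms: an ellipsoidal lesion (default radius 7 mm, darker constant
background, additive Gaussian noise, default grid 64×64×7 voxels at
0.548×0.548×3 mm) filled with a Gaussian random field — white noise
smoothed at the class's correlation length, standardised, and passed
through the monotone transform (exp(a·z) − 1)/a whose shape parameter a
controls skewness/kurtosis. Correlation length drives GLCM/fractal/LoG
features, the transform drives first-order shape features, so all families
can carry class signal without modelling MR physics. Defaults mirror the
study conditions: 183 cases, prevalence 74/183; class texture defaults
(correlation lengths 1.5 vs 3.0 mm, shapes 0 vs 0.8) are package choices —
no quantitative description of responder/non-responder texture differences
exists to calibrate against, so effect sizes are free knobs. Setting both
class parameter sets equal (`spec.null()`) yields an exact null cohort. All
randomness flows from the single spec seed through one named generator;
equal specs reproduce bitwise-identical voxels.

`generate_feature_table` is the fast mode: it draws the case × feature
matrix directly (informative columns shifted by a standardised mean
difference, optional duplicate columns and block correlation for exercising
the pruning stage) and is what the selection/modelling test conditions use.
What the phantoms do **not** emulate: scanner/protocol heterogeneity, bias
fields, partial-volume effects, anatomical context, or contouring
variability — passing tests demonstrate correctness and calibration of the
pipeline, not clinical performance on real MRI.

## Measured behaviour of the reproduced protocol

On null cohorts (no class signal), per-feature p-values are uniform and the
stability vote count averages ≈ 8α per feature; the stability stage is at
least as strict as a single-pass α = 0.05 screen (measured over 20
replicates at n = 180, 500 features). Five planted features at SMD = 2
among 495 nulls are fully recovered in ≥ 18/20 replicates.

Because selection precedes CV on the same data, an end-to-end run on a
*null* cohort (n = 160, 300 noise features) still reaches winner mean CV
AUCs of roughly 0.75–0.87 across seeds — a measured, pinned illustration of
the protocol's selection bias, far above the ≈ 0.5 obtained when the same
classifiers are cross-validated on features fixed independently of the
data. Strong-signal cohorts (5 informative features, SMD = 2, n = 120)
reach winner mean CV AUC ≥ 0.85. Users interpreting CV AUCs from this
protocol on real data should expect the same optimism.

## Problem sizes and numerical conventions

Tests and the acceptance script run at deliberately modest sizes chosen to
exercise every stage with stable statistics: feature tables of 64–200 cases
and up to 1000 features, phantom grids of 40–64 px planes and ~6 slices,
full 15-model roster runs at n = 120–183. Tolerances in tests follow the
estimator's sampling noise (e.g. ±3 Monte-Carlo SDs for null AUC means,
where the MC SD ≈ 0.10 is dominated by a finite table's spurious
class-feature association). Degenerate inputs have fixed conventions:
constant ROI → normalisation error; constant feature → p = 1; empty
subpopulation → NaN sentinel; GLCM correlation with zero variance → 0;
single-pixel slice → fractal dimension 0.

## Known limitations

* The feature census is configuration-defined, not a reproduction of the
  original 1889-feature bank (which is not enumerable from its description).
* Classifier equivalents are nearest-standard-library mappings, not ports
  of the original R implementations; their default hyperparameters differ.
* Selection-before-CV is reproduced faithfully, including its optimism; no
  nested re-selection is offered.
* No confidence intervals on AUC; variability is reported as the SD over
  the 24 CV folds only.
* Reported clinical-scale operating characteristics depend entirely on the
  synthetic effect sizes chosen; they say nothing about real cohorts.
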