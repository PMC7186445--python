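# Methods

## Problem and data model

The package models the risk of late subcutaneous fibrosis after partial
breast irradiation from two voxel fields defined on a common isotropic
grid: the relative electron density (RED, from planning CT) and the
biologically effective dose (BED, from the planned dose grid), each
analysed inside two regions of interest (the whole breast and the PTV).
All volumes live in `VolumeGrid` objects — a 3D array indexed `[z, y, x]`
with spacing and origin in mm, voxel *centres* at `origin + index·spacing`;
masks are defined by centre inclusion. DICOM CT series and RTDOSE grids
are read with pydicom; research volumes round-trip through SimpleITK
(NIfTI/NRRD). Readers reject inconsistent geometry (mixed series,
non-uniform slice spacing) rather than truncating.

Because the analysis compares ROI features across RED and BED, both
volumes and both masks are resampled onto one lattice: the 3 mm isotropic
grid derived from the CT (trilinear for intensities, nearest-neighbour for
masks, physical extent preserved within one voxel). Which source grid
serves as the common lattice is a genuine design choice; using a single
shared grid is the only construction under which "the same ROI" is
well-defined for both images.

## Physical conversions

* **HU → RED**: piecewise-linear interpolation through the scanner's
  measured calibration points; outside the table the terminal segment is
  continued linearly and clamped at 0 (densities cannot be negative).
* **Dose → BED**: per voxel with total dose `D` delivered in `n` fractions,
  `BED = D(1 + (D/n)/(α/β))`, i.e. the voxel's fraction size is `D/n` and
  every fraction is assumed equal. `α/β = 3 Gy` by default (late-responding
  subcutaneous tissue). BED is monotone in `D` and exceeds `D` whenever
  `D > 0`. The three clinical regimens (40 Gy/10, 35 Gy/7, 28 Gy/4) share
  the prescription-point BED 93.33 Gy, so the conversion places all
  fractionation schemes on one scale.

## Feature extraction

Filters are applied before discretization: Gaussian and
Laplacian-of-Gaussian with σ = 3 mm (converted to voxels per axis, so
anisotropic grids blur isotropically in physical space), and a 3×3×3
voxel median; scales are configurable. Each filtered image is discretized
per ROI into 64 equal-width bins over the in-ROI min–max
(`level = 1 + ⌊64(x−min)/(max−min)⌋`, maximum mapped into the top bin), so
discretization is invariant to positive affine rescaling and each filter
output gets its own range.

The fixed catalog is 21 shape features per ROI plus 57 intensity features
per (image, ROI, filter): 18 first-order, 25 co-occurrence (GLCM) and 14
run-length (GLRLM) — `21·2 + 57·2·2·4 = 954` columns, named
`<image>_<filter>_<roi>_<family>_<feature>` (shape:
`shape_<roi>_<feature>`). The catalog deliberately contains every feature
the selection stage is expected to surface (cluster shade, RLN and RLNN,
kurtosis, range, 10th percentile, inverse variance, variance).

Conventions worth stating:

* **GLCM**: distance-1 pairs over the 13 unique 3D directions,
  symmetrized, *merged* into a single 64×64 matrix, then normalized.
  Cluster shade is the third central co-occurrence moment
  `Σ (i+j−μ_i−μ_j)³ p(i,j)` (zero for level-symmetric textures, sign
  flipping under level mirroring); inverse variance is
  `Σ_{i≠j} p(i,j)/(i−j)²`. A single-level ROI yields cluster shade 0 and a
  flagged correlation of 0.
* **GLRLM**: runs of equal level per direction, broken by ROI exit, summed
  over the 13 directions. Both the run-length non-uniformity
  `RLN = Σ_j (Σ_i r_{ij})²/N_r` and its normalized variant
  `RLNN = …/N_r²` are emitted; run percentage uses `13·N_v` as its
  denominator so a fully fragmented ROI scores exactly 1.
* **First order**: excess-kurtosis convention; percentiles by linear
  interpolation; entropy/uniformity on the 64-bin in-ROI histogram;
  zero-variance ROIs return flagged zeros for skewness/kurtosis instead of
  NaN so downstream selection never crashes.
* **Shape**: surface area and mesh volume come from a marching-cubes mesh
  of the mask indicator smoothed by a 0.8-voxel Gaussian before taking the
  0.5-isosurface. The raw voxel staircase overestimates surface area by
  ~10 % (a digital r = 10 sphere scores sphericity 0.91); with the
  anti-aliased isosurface it scores 0.99 against the analytic sphere.
  Axis lengths derive from the voxel-coordinate covariance eigenvalues;
  the centre-of-mass shift uses the unfiltered RED as the intensity
  weighting.

Correctness of both texture families is pinned to brute-force oracles
(explicit pair enumeration and run scans) at 1e-10 relative tolerance on
random 5×5×5 grids, including ROIs with holes.

## Class balancing (ADASYN)

With `n_maj`/`n_min` class counts and balance level β, the synthetic
budget is `G = β(n_maj − n_min)`. Each minority point receives
`g_i = round(r̂_i·G)` children, where `r_i = Δ_i/k` is the fraction of
majority points among its k = 5 nearest neighbours over all classes and
`r̂` normalizes `r` to sum to one; children are convex combinations
`x_i + λ(x_z − x_i)`, λ ~ U(0,1), with `x_z` drawn uniformly from the k
nearest *minority* neighbours. Distances are Euclidean on z-scored
features — radiomic columns span many orders of magnitude (cluster shade
~10⁴ vs normalized RLN ~0.5) and would otherwise dominate — while
synthesis happens in original units. If no minority point has majority
neighbours the allocation falls back to uniform with a warning.

Per-instance round-half-up makes the synthetic total drift from `G` by a
few rows; the balance contract is therefore "≈50 % minority share", not an
exact row count (on the 124/41 cohort mix the augmented share lands at
49–51 % depending on the draw). Orchestration layers clamp k to
`n_min − 1` so small training folds remain augmentable; the estimator
itself keeps the strict `n_min ≥ k+1` precondition.

## Selection and classifiers

Stepwise forward selection is a wrapper on an unpenalized logistic GLM:
at each step every unused candidate is scored by the mean out-of-fold
binomial deviance over one fixed, seeded, stratified 5-fold split (shared
across candidates within a step, so comparisons are paired), and the
minimizer is added; ties break on lexicographic name, making the result
invariant to column order. Optional backward passes remove features that
lower the criterion further. Because forward selection without backward
steps is nested, the pipeline's scan over the allowed number of variables
(4–8) runs selection once to the largest cap and evaluates prefixes.

* **SVM**: RBF kernel on z-scored features; box constraint and kernel
  scale chosen on a seeded log grid (10⁻³–10³) by 5-fold CV
  misclassification; score = signed decision value, threshold 0.
* **Ensemble (EML)**: decision-tree weak learners; seeded random search
  over {random forest, AdaBoost, LogitBoost (stagewise log-loss boosting),
  GentleBoost (exponential loss), RUSBoost (AdaBoost on a balanced
  undersample)} × (cycles, learning rate, minimum leaf size); candidates
  that fail to boost ("worse than random" on small folds) are skipped;
  score = positive-class probability, threshold 0.5.
* **Naive Bayes**: per-feature class-conditional densities, Gaussian or
  Gaussian-kernel with bandwidth factor ∈ {0.5, 1, 2} × Silverman's rule,
  chosen by seeded CV; empirical priors; posterior score, threshold 0.5.
  A class-constant feature falls back to a minimum-bandwidth kernel.

All three trainers are deterministic given (data, features, seed, budget)
and store their standardization so original-unit rows score correctly.

## Evaluation

`auc` is the Mann–Whitney statistic (midranks, ties = ½), cross-checked in
tests against pair enumeration and trapezoidal ROC integration. Repeated
CV draws a fresh seeded stratified 5-fold split per repeat, pools
out-of-fold scores into one sensitivity/specificity/AUC per repeat, and
reports means with empirical 2.5/97.5 percentiles. Note the percentile
interval *widens* toward its population value as repeats grow — with few
repeats the empirical 2.5/97.5 quantiles sit near the sample extremes —
so interval width is a convergent, not monotone-shrinking, quantity.

Two augmentation placements are provided. `paper` mode augments the whole
table once and cross-validates the augmented rows — the procedure the
clinical analysis describes, but optimistic, because synthetic neighbours
of test points enter training; `safe` mode augments inside each training
fold only. The paired test documents the direction of this leakage
(paper-mode AUC ≥ safe-mode AUC on average), and a `safe`-mode run on
signal-free cohorts is calibrated (mean AUC within 0.5 ± 0.06 at n = 300).

Resubstitution metrics on the original rows (`evaluate_on_original`)
deliberately reproduce the pathology of overfit ensembles: a deep tree
trained on an augmented set containing the originals scores 1.00/1.00/1.00.
Univariate screens use the chi-square independence test for categoricals
(Yates-corrected 2×2) and the two-sided Wilcoxon–Mann–Whitney test for
continuous variables (exact below 15 per group, tie-corrected normal
approximation otherwise).

The acceptance gate accepts a model iff mean sensitivity ≥ 0.75, mean
specificity ≥ 0.75, mean AUC ≥ 0.85 (all with ≥ semantics) *and* the
dose–response vetting passes: the score, evaluated on a 100-point grid
over the observed range of a chosen BED feature with every other selected
feature pinned to a profile (cohort mean, or the mean of the extreme
low-/high-score patients), must be non-decreasing up to 10⁻⁶ of the score
range. Extreme-score profiling takes the ceiling-rounded 5 % of negatives
with the lowest scores and positives with the highest, with stable-order
tie-breaks.

## Synthetic cohorts

Image-level phantoms emulate the study conditions: 165 patients at 24.8 %
positive prevalence by default, fractionation mix 73:60:32 over the three
regimens. The breast is a half-ellipsoid against a chest-wall plane,
surrounded by air; in-breast HU is a two-component fat/gland field
(−100/+40 HU) obtained by thresholding a Gaussian-correlated random field
(6 mm correlation length) at a per-patient gland fraction (U(0.2, 0.6)),
plus 20 HU white noise. The PTV is a sphere (10–16 mm radius, capped by
breast size) placed to respect a 5 mm skin margin; dose is the
prescription over the PTV with a logistic penumbra of 5 mm scale, and with
probability 0.3 a Gaussian hot spot of 8–15 % amplitude. Outcomes are
Bernoulli draws from a logistic model on cohort-standardized features
(defaults: +1.5 on the PTV-BED 10th percentile, −1.0 on PTV-RED kurtosis,
mirroring the direction of the selected clinical features), with the
intercept calibrated by root finding so the expected prevalence matches
the target. A fast path generates class-conditional multivariate-normal
feature tables directly for testing the tabular stages.

What the phantoms do **not** model: anthropomorphic anatomy, heterogeneity
beyond the two-component mixture, realistic beam arrangements or Monte
Carlo dose, inter-feature correlation structures of real radiomics, and
scanner artefacts. Passing tests therefore demonstrate that the pipeline's
statistics behave as designed under known generating mechanisms — signal
recovery, null calibration, leakage direction — not that the clinical
effect sizes are reproduced; the clinical cohort is not distributed and
its Table-level values are not targets.

## Numerical choices and problem sizes

Seeds fan out from one global seed through per-stage `SeedSequence` keys
(stage-name CRC plus indices), so every artifact is reproducible byte for
byte and stage reordering cannot silently reuse a stream. Deviance uses
probability clipping at 1e-10; GLM non-convergence scores a candidate +∞.
Default search budgets are 400 (SVM grid) and 60 (ensemble draws); the
test and acceptance configurations use reduced problem sizes chosen to
exercise every code path at statistically meaningful scale — 5×5×5 texture
oracles, n = 300 cohorts with 25–50 seed replicates for
recovery/calibration, 16-patient phantom runs for the end-to-end smoke
test — sizes at which each asserted property has comfortable statistical
margin.

Known limitations: the 57-feature split per family is one defensible
reading of the printed totals; GLCM aggregation fixed to the merged
convention; the discretization of BED follows the same 64-bin scheme as
RED; stepwise selection defaults to running on the augmented table (a
flag switches it to the original); and the monotonicity vet inspects one
BED feature at a time along an axis-aligned section of feature space.
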