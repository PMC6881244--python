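# Methods

`hipporad` implements a hippocampus-radiomics diagnostic pipeline for
discriminating amnestic mild cognitive impairment (aMCI) from normal
controls (NC) on structural T1-weighted MR: a 385-feature radiomic
catalog computed from a masked 3D volume, a three-stage
feature-selection cascade, and logistic-regression classification
evaluated over repeated stratified splits. Because no patient data are
distributed, a synthetic-cohort generator provides fully controlled
inputs for every stage; this note records the models, conventions and
numerical choices, and what the synthetic results do and do not show.

## Feature extraction

**Discretization.** In-mask intensities are binned into G = 64
equal-width gray levels over the ROI min–max range (configurable in
the catalog config). A constant ROI maps entirely to level 1. The
min–max fixed-bin-count scheme is the conservative default where the
upstream software's discretization is unspecified; it is recorded in
the catalog config so alternates can be swapped without code changes.

**Histogram (42 features).** First-order statistics of the raw ROI
intensities plus statistics of the 64-bin probability vector p:
moments (population normalization; kurtosis is the non-excess Pearson
form; skewness/kurtosis of a zero-variance ROI are defined as 0),
order statistics and percentiles, energy Σx², entropy −Σp·log₂p (bits),
uniformity Σp², maximum probability, and the mode as the center of the
most populated bin. Note one terminological trap: uniformity as
defined here (Σp²) is *maximal* for a homogeneous region; descriptions
of it as rising with image complexity refer to the complement.

**Form factor (9 features).** Size/shape descriptors of the binary
mask in physical mm units: voxel count, volume (count × voxel volume),
surface area by exposed-voxel-face counting, surface-to-volume ratio,
maximum 3D diameter (largest Euclidean distance between boundary-voxel
centers, accelerated through the convex hull for large masks),
sphericity, two compactness variants, and spherical disproportion.
Face counting makes toy-mask values closed-form (one 1 mm voxel has
surface 6 mm², ratio 6) but biases surface estimates upward by a
bounded factor relative to mesh-based (marching-cubes) estimates; the
convention is deliberate and consistent across subjects, which is what
a between-group comparison needs.

**GLCM (8 base × 6 direction variants × 3 offsets = 144).** Voxel
pairs are counted per axial slice along four in-plane directions (0°,
45°, 90°, 135°) at offsets 1, 4 and 7 voxels, accumulated over slices,
symmetrized and normalized. Per-slice 2D sampling with four angles
(rather than 13-direction 3D) matches the four-direction convention
of the reference workflow; the direction set is a module constant.
Base statistics: energy, entropy, inertia (contrast), correlation,
inverse difference moment, cluster shade, cluster prominence, and
Haralick correlation. Correlation of a zero-variance matrix is 0 by
convention. Haralick correlation is implemented as the gray-level
covariance Σij·p(i,j) − μ² — the normalized textbook form is
algebraically identical to the correlation feature on a symmetrized
matrix and would duplicate a column. Each per-direction value is also
aggregated across the four directions by arithmetic mean and
population SD, named `<Base>_All Direction_offset<d>` and `..._SD`.

**Haralick block (10 features, offset 1).** Sum/difference statistics
of the offset-1 GLCM averaged over the four directions: sum
average/entropy/variance, difference average/entropy/variance, the two
information measures of correlation (log₂ entropies; IMC2 uses
√(1−e^{−2(HXY2−HXY)}) clipped at 0), autocorrelation and maximum
probability. Sum variance is centered on the sum average.

**Run-length (10 base × 6 variants × 3 offsets = 180).** Runs are
maximal sequences of equal gray level encountered when a slice line is
traversed along a direction visiting every d-th voxel; out-of-mask
voxels break runs. At stride 1 this is the classical Galloway matrix;
the stride generalization mirrors the offset applied to the GLCM. The
ten statistics are the run-count-normalized family (short/long run
emphasis, gray-level and run-length nonuniformity, low/high gray-level
emphasis and the four joint variants). Run percentage — the one
classical statistic normalized by voxel count instead of run count —
is not in the default catalog.

**Missing values.** A thin ROI may admit no voxel pair at offset 4 or
7; such GLCM entries (and their aggregates) are emitted as NaN and
resolved by the selection stage's mean imputation, mirroring the
replace-abnormal-values-by-mean preprocessing convention. RLM values
remain defined whenever at least one (possibly length-1) run exists.

The full catalog is 42 + 9 + 144 + 10 + 180 = 385 features. Only the
total and the five families are externally fixed; the per-family split
is this package's declared enumeration, versioned in the catalog
config.

## Feature selection

Preprocessing: non-finite entries are imputed by the feature's mean
over finite training entries; the cohort is split stratified 0.7/0.3
(per class, round(0.7·n) rows train, so 42+44 subjects give 29+31
train and 13+13 test); features are z-scored with training statistics
only, and zero-variance training features dropped.

1. **Univariate screen.** Welch t-test and Mann–Whitney rank test per
   feature at α = 0.05, no multiple-testing correction (a BH-FDR flag
   exists for users). Survivors are the union of the two tests'
   survivor sets; intersection is configurable. Union is the default
   reading of "integrating" two tests — an intersection would make the
   rank test a pure veto.
2. **Redundancy filter.** All unordered pairs with |Spearman ρ| > 0.9
   are visited in descending |ρ| (ties broken by name); for each pair
   whose members are both still alive, one is removed by a seeded coin
   flip, and the (kept, removed, ρ) triple logged.
3. **Cross-validated LASSO.** An L1-penalized logistic path over a
   40-point log-spaced grid λ ∈ [10⁻³, 10²] with the objective mean
   deviance + λ‖w‖₁ (liblinear, tol 10⁻⁶), stratified 10-fold CV;
   the λ minimizing mean CV deviance is chosen and features with
   nonzero coefficients there survive. The λ value is reported in this
   parameterization; penalty scalings are software-specific and are
   not comparable across implementations.

Every stochastic point (split, coin flips, fold assignment) is driven
by an explicit seed, and all statistics are computed from training
rows only — the fitted cascade is invariant to arbitrary perturbation
of test rows, which the suite asserts directly.

## Classification and evaluation

The final model is *unpenalized* maximum-likelihood logistic
regression on the selected features (selection and estimation are
separated; refitting without the L1 penalty is the standard two-stage
reading). Under perfect separation the MLE diverges; the fit falls
back to a tiny ridge (C = 10³) and flags the report. A subject's
radiomics score is the linear predictor; the probability is its
sigmoid, thresholded at 0.5 (equivalently, score 0).

Evaluation repeats 10 shuffled stratified 0.7/0.3 splits: refit on
train, evaluate on train and test, report AUC, specificity,
sensitivity, PPV, NPV, precision, recall and F-score per repetition
and as mean ± SD, plus the train−test AUC gap as an overfitting
indicator. AUC uses the midrank Mann–Whitney normalization (ties at
n = 26 test subjects make the tie convention material); the identity
with the trapezoid ROC area is asserted in the suite. Left and right
hippocampus models are fully independent fits from the same manifest.

## Cohort statistics

Demographic comparisons use the pooled-variance (Student) two-sample
t-test by default — the convention of standard SPSS output, and the
variant that reproduces the reference summaries' printed statistics
(age t = −0.58, education t = 0.96 from the printed mean/SD/n) —
with Welch available via a flag. Sex uses the Pearson χ² on the 2×2
table without continuity correction (χ² = 0.06 on 18:24 vs 20:24);
Yates' correction is available but changes the printed value.
Statistics recomputed from *rounded* printed summaries can differ from
values computed on raw data in the last digit (the MMSE row is the
extreme case, |t| ≈ 17.9); the package asserts only what the rounded
summaries support.

## Synthetic cohort generator

Each subject is a Gaussian-random-field volume: white noise smoothed
by an isotropic Gaussian kernel of width σ_tex voxels, rescaled to
exact sample mean μ and SD s, plus independent additive N(0, σ_noise)
voxel noise. The ROI is an ellipsoid (semi-axes in mm, long axis
anterior–posterior) whose radius is jittered by a smooth random field
(amplitude in mm), with mirrored left/right centers about the
mid-sagittal plane. Between-subject heterogeneity comes from
subject-level lognormal jitter on size (5%), intensity spread (8%)
and smoothness (8%), and additive jitter on the mean (SD 5): without
it any group effect would separate perfectly, which no patient cohort
does.

Each generator knob maps onto a feature family monotonically: the
semi-axes drive the form-factor features, σ_tex drives GLCM/RLM
(smoother fields have more similar neighbors, so e.g. the inverse
difference moment rises with σ_tex — asserted across σ_tex ∈ {0,1,2,3}),
and s drives the histogram spread statistics.

Defaults define a cohort of 42 cases vs 44 controls on a 32×32×28 grid
of 1 mm voxels; cases have 4% smaller semi-axes, σ_tex 1.82 vs 2.0,
and s 21.5 vs 20. These effect sizes are a one-time calibration chosen
so the end-to-end pipeline lands in a mid-range test AUC (≈ 0.75–0.85)
comparable to published hippocampal radiomics performance; they are a
property of the generator, not a measurement of patients. The grid is
deliberately small — it keeps a full 86-subject run under a minute on
one core while leaving ROIs of ≈ 1 000 voxels, large enough for
offset-7 statistics to exist.

What the synthetic cohort does *not* emulate: anatomically realistic
hippocampal shape, MR bias fields and Rician noise, partial-volume
effects, registration error, or any correlation between demographics
and the image phenotype (the generated age/sex/education carry no
planted group effect; MMSE does, by construction of the diagnostic
groups). Passing end-to-end tests therefore demonstrates that the
pipeline machinery is correct and well calibrated under a known
generative model — not that its discrimination estimates transfer to
real MRI.

## Numerical conventions and degenerate inputs

- Entropies in bits (log₂); 0·log 0 terms excluded.
- Population (ddof = 0) SDs in feature aggregation and moments;
  sample (ddof = 1) SDs in the demographics table, matching summary
  statistics as usually printed.
- Quantized level of the ROI maximum is clipped into bin G.
- GLCM with an empty pair set → None → NaN features; a direction
  missing from an All-Direction aggregate is excluded; all four
  missing → NaN.
- Correlation of a degenerate GLCM is 0; IMC1 is 0 when the marginal
  entropy vanishes; IMC2 is clipped at 0 before the square root.
- Spacing comparisons between volume and mask use 10⁻⁴ mm absolute
  tolerance (NIfTI headers round-trip through float32).
- Seeds: a master seed is hashed (SHA-256) with the stage name into
  per-stage seeds < 2³¹, so any stage can be rerun in isolation.

## Known limitations

- Per-slice 2D texture sampling ignores the through-plane direction;
  a 13-direction 3D mode would require a new direction table but no
  structural change.
- The catalog's per-family split beyond the fixed total of 385 is an
  enumeration choice; other software's 385 need not coincide.
- Surface area is a voxel-face count (upward-biased vs mesh methods).
- The LASSO λ is not comparable to values printed by other software.
- Printed-summary statistics are reproducible only to the precision
  the rounding admits (one unit in the last printed digit).
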