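# Methods

This note documents the models, the numerical choices, and what the
synthetic data can and cannot show. All defaults cited here are the values
in the code; nothing below reports a number the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis chain

The package analyses *skeletonized FA images*: 3D volumes, zero off a thin
white-matter skeleton, with FA values in [0, 1] on it. Tensor-derived scalar
maps follow the standard definitions: FA is the normalized eigenvalue
dispersion `sqrt(1/2)·sqrt((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²)/sqrt(λ1²+λ2²+λ3²)`,
axial diffusivity is λ1, radial diffusivity is (λ2+λ3)/2. Eigenvalues are
sorted descending internally; negative values (possible in noisy tensor
fits) are clamped to zero with a warning; all-zero voxels get FA = 0 by
convention. Skeleton thresholding is strict (`FA > 0.2`), so a voxel at
exactly the threshold is excluded. The common mask across subjects keeps
voxels that are nonzero and finite in every image; its voxel count is
data-dependent and logged, never asserted. Feature matrices enumerate mask
voxels in C (row-major) ravel order, a fixed, documented bijection between
columns and voxel coordinates.

## Linear SVM

The classifier is the standard soft-margin linear SVM with C = 1,
deliberately untuned: with far more voxels than subjects the solution is
insensitive to C over a wide range, and tuning would require nested
cross-validation without serving the purpose of an out-of-the-box
single-subject analysis. The problem is solved in the dual on the
subjects-sized Gram matrix with a most-violating-pair SMO scheme
(first-order working-set selection, analytic two-variable updates, KKT-gap
stopping at tolerance 1e-6, iteration cap 10,000 with a hard error on
exhaustion). The bias is the mean of the KKT-implied values over free
support vectors, or the midpoint of the violating-pair bounds if none is
free. The primal weight vector `w = Σᵢ αᵢ yᵢ xᵢ` is reconstructed for the
weight map; the duality gap of the reconstructed primal is bounded by the
stopping tolerance (checked in tests against a generic quadratic-programming
solve and against scikit-learn). Decision ties (f = 0) go to the control
class: deterministic, and conservative about diagnosing. No feature scaling
or centering is applied by default; an optional switch mean-centers with
training-fold statistics only.

Gram-matrix reuse matters for speed: cross-validation and permutation
testing compute the full-cohort Gram matrix once and train each fold on a
submatrix, so a 200-permutation run over 77 folds completes in about a
minute on one CPU.

## Cross-validation and permutation inference

Folds follow the matched design: each fold's test set is one patient plus
their age/sex-matched control, all remaining subjects train. Accuracy,
sensitivity and specificity are exact ratios of integer counts; percentages
are reported to two decimals.

The permutation null reruns the *entire* cross-validation on relabeled
cohorts. Two schemes are provided, because "randomly assigned to a group"
admits both readings: the default flips patient/control labels
independently within each matched pair (the exchangeable unit of a matched
design, preserving group sizes and pairing), and a pooled scheme permutes
the label vector over all subjects. The p-value is the strictly-greater
proportion `#{null > observed}/n_perm`; an add-one (b+1)/(m+1) estimator is
available behind a flag and used in documentation examples to avoid p = 0.
Sensitivity and specificity p-values come from the same permutation runs.

## Clinical associations

Three analyses relate classifier behaviour to clinical variables (PANSS
subscales sampled around means 13.9/15.7/32.8 with SDs 4.9/6.1/8.5,
chlorpromazine-equivalent dose log-normal around a median of 337 mg/day,
one dose deliberately missing): a pooled-variance Student t comparing
correctly vs incorrectly classified patients (df = n1+n2−2), Pearson
correlation between Platt posteriors and each variable, and linear-kernel
ridge regression predicting each variable from the voxel pattern. Platt
scaling is fit on pooled out-of-fold decision values with the smoothed
targets t+ = (N+ + 1)/(N+ + 2), t− = 1/(N− + 2), by damped Newton iteration.
Missing values are dropped pairwise, so degrees of freedom track the usable
sample per variable.

Kernel ridge regression uses the closed form `α = (K + λI)⁻¹y`. Three
numerical choices here were genuinely open and deserve their rationale:

* **Kernel normalization.** The Gram matrix is divided by its mean diagonal
  element (trace/n) rather than by the voxel count. After fold-centering,
  voxel-count normalization leaves kernel entries at the ~1e-4 scale of the
  FA noise variance, so any O(1) ridge annihilates the predictions;
  trace-normalization makes λ a scale-free amount of shrinkage.
* **Ridge default λ = 0.1.** Out-of-sample evaluation is leave-one-out with
  the training-fold mean added back, and that fold mean is mechanically
  anti-correlated with the held-out value (`ȳ₋ᵢ = (S − yᵢ)/(n−1)`). If
  shrinkage drives the kernel part of the prediction to zero, the
  correlation between predictions and observations converges to −1 under
  the null. A light ridge keeps prediction variance comparable to the
  target's, which dilutes the artifact to the small negative bias seen in
  the null simulations; the remaining bias is a property of leave-one-out
  correlation scoring, not of the estimator.
* **Fold centering.** `krr_cv_predict` centers features and targets on the
  training fold (train/test separation preserved); `krr_fit` itself stays
  the plain closed form so its algebra matches the textbook identity and
  the primal-ridge equivalence checked in tests.

Evaluation runs leave-one-out over patients because the clinical variables
exist only for patients; performance is the Pearson r between out-of-fold
predictions and observations.

## Group statistics

The voxelwise statistic is the pooled-variance two-sample t, oriented so
positive values support the requested direction; both one-sided directions
are run separately. Zero-variance voxels get t = 0 with a warning. TFCE
uses E = 0.5, H = 2, 26-connectivity and dh = max(t)/100 by default (the
conventions of the FSL randomise tool); the integration runs over
h = dh, 2dh, …, max, with an ulp-scale tolerance at the top step so the
maximum voxel is not lost to floating-point rounding. Negative statistics
contribute nothing. dh ≥ max(t) is an error (no integration steps); an
all-zero statistic image maps to an all-zero enhancement.

FWE correction permutes group labels over the pooled subjects (group sizes
preserved), records the image-wide maximum enhanced statistic per
permutation, and sets the per-voxel corrected p to
`(#{null maxima ≥ observed} + 1)/(n_perm + 1)` — the convention that counts
the observed labeling, guaranteeing p > 0, and deliberately different from
the classification module's strictly-greater convention; both are
documented where they apply. Clusters are connected components of
{p < α} with size, peak (minimum-p) voxel in 0-based grid indices, and peak
p. Default 1000 permutations, configurable; the calibration tests use 200.

## The synthetic cohort generator

The generator emulates the *structure* the analyses rely on, not anatomy:

* **Skeleton**: a branching self-avoiding random walk grown from the grid
  centre until it covers the requested fraction of voxels — connected,
  width one, curvilinear. Baseline FA per skeleton voxel is uniform on
  [0.25, 0.8], safely above the 0.2 threshold.
* **Groups**: patient images subtract `effect_delta` inside an effect
  region built from random spheres intersected with the skeleton and
  trimmed to cover exactly `effect_fraction` of it; both groups add i.i.d.
  Gaussian voxel noise (SD `noise_sd`) and clip to [0, 1]. A warning fires
  if more than 1% of skeleton voxels clip to zero. Patients additionally
  carry a per-subject severity scale on the effect amplitude,
  `δᵢ = effect_delta · max(0, 1 + 0.3·N(0,1))`: without between-patient
  variation in the image pattern, clinical scores coupled to the images
  would be information-theoretically unrecoverable by any regression, since
  the only subject-level image variation would be isotropic voxel noise.
  The group-mean effect and the `effect_delta = 0` null are unaffected.
* **Pairs**: each pair shares an age drawn from 18–45 and a sex; labels are
  exchangeable within pairs when the effect is zero.
* **Clinical scores**: truncated Gaussians around the published cohort
  descriptives; `clinical_coupling` c mixes a standardized loading on the
  patient's observed mean FA in the effect region (lower FA, higher
  severity) with independent noise as `c·z + sqrt(1−c²)·ε`.

Defaults are the study conditions: 77 pairs, effect over 20% of the
skeleton, FA reduction 0.05, noise SD 0.02, no clinical coupling. Under
these conditions the synthetic cohort is *much* easier to classify than a
real first-episode cohort (cross-validated accuracy near 100% versus the
low-60s typical of real data): real FA maps have spatially correlated
noise, registration error, biological heterogeneity beyond a scaled common
pattern, and site effects, none of which are modelled. Passing tests
therefore validate the *correctness of the machinery* — fold bookkeeping,
solver optimality, calibration of the permutation and FWE procedures,
recovery when signal is present — not the expected effect sizes on real
cohorts.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks run at deliberately modest scale, chosen so the
suite stays interactive while the Monte-Carlo tolerances remain meaningful:
null calibration uses 50 repetitions of 10-pair (type-I error) and 8-pair
(FWE) cohorts on a ~90-voxel skeleton with 200 permutations each; recovery
checks use 40 pairs on an ~800-voxel skeleton. The acceptance script runs
the full 77-pair design on the 800-voxel skeleton with 200 permutations for
both the classification and group-statistics nulls.

## Known limitations

* No registration, skeleton-projection or tensor-fitting machinery: the
  generator emulates their *output*, and real-data preprocessing must come
  from standard neuroimaging tools.
* The permutation wording ambiguity (within-pair vs pooled relabeling) is
  resolved by configuration, not adjudicated; results for both schemes
  agree under the null by design.
* Leave-one-out correlation scoring of the clinical regression carries a
  small negative bias under the null (see above); interpret small negative
  r values accordingly.
* Peak coordinates in cluster tables are voxel indices of the synthetic
  grid; they are not comparable to template-space coordinates of real
  studies.
* The generator's clinical scores couple to a single image pattern; real
  symptom dimensions are not low-rank functions of FA.
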