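# Methods

This note documents the models, conventions and numerical choices behind
`m3class`, and what the synthetic-data tests do and do not establish about
real imaging data.

## Voxelwise metrics

**Order of operations.** Nuisance regression comes first; band-pass
filtering second. ALFF is computed from the *unfiltered* (nuisance-regressed)
series, because the metric itself integrates a frequency band and filtering
first would make it tautological. ReHo and degree centrality consume the
band-passed series; ReHo is computed before any smoothing (smoothing would
inflate local rank concordance by construction).

**Nuisance model.** The design is [intercept | 24-parameter Friston motion
expansion [p, p², p_{t−1}, p_{t−1}²] | WM signal | CSF signal | linear
ramp | optional global signal]. Residuals come from one least-squares solve
per voxel; the linear drift is a ramp covariate inside the same design
rather than a separate detrend pass (same column span, one solve). A
rank-deficient design triggers a warning and the pseudoinverse solution.
Regressing the global signal is idempotent: the residual mean in-mask series
is already constant.

**Band-pass.** An ideal rectangular filter in the discrete Fourier domain:
bins with low ≤ f ≤ high survive, all others (including DC when low > 0)
are zeroed. This is the parameter-free convention of the standard
resting-state toolchains and is exactly invertible on in-band content.

**ALFF** is the mean of the amplitude spectrum (2|F_k|/N, the square-rooted
periodogram) over 0.01–0.10 Hz. A constant series has no in-band power and
maps to 0.

**ReHo** is Kendall's coefficient of concordance
W = 12 S / (K² (n³ − n)) over the ranked series of the K in-mask voxels of
the 7/19/27-voxel neighborhood (center included), with S the squared
deviation of per-timepoint rank sums around K(n+1)/2. K shrinks at mask
edges; voxels with K < 2 get W = 0 and are counted in the log. No tie
correction is applied (midranks are used; exact ties are measure-zero for
continuous data).

**Degree centrality** counts, per voxel, the other in-mask voxels with
Pearson r strictly greater than the threshold (default 0.25, one-sided:
anticorrelations never count); `weighted=True` sums those r values instead.
Zero-variance voxels are treated as r = 0 and logged.

**VMHC** correlates each voxel with its partner mirrored across the first
spatial axis (x → X−1−x on a 0-based grid), requiring an even x-extent.
Synthetic volumes are built mirror-symmetric, standing in for the symmetric
template registration that real pipelines perform upstream. Voxels whose
partner leaves the mask are excluded (0, logged), keeping the map symmetric.

**Standardization.** "Fisher-Z" is applied as atanh(r) (with |r| clamped to
1 − 10⁻⁷) only to correlation-valued maps (VMHC). ALFF, ReHo and DC are not
correlations — atanh is undefined for them — so they are standardized as
within-mask (x − mean)/SD z-maps, the convention the standard toolboxes use
for their "zMap" outputs. This split is an informed convention choice, not
something the method uniquely determines.

**Smoothing** is a separable Gaussian with σ = FWHM/(2√(2 ln 2)) per axis in
voxel units, with nearest-edge padding so constant maps stay exactly
constant; FWHM 0 is the identity. Typical use: 4 mm on the functional
z-maps (not VMHC, which is smoothed upstream before correlation), 8 mm on
grey-matter density.

Tissue segmentation is out of scope: grey-matter density maps enter as
ready 3D volumes (synthetic or user NIfTI).

## Feature extraction

One value per (modality, region): the mean over voxels carrying the region's
atlas label *and* lying inside the analysis mask (consistent with the
in-mask metric computation). Ordering is fixed modality-major
(ALFF, ReHo, DC, VMHC, GMD) with regions in ascending label order, so column
identity is deterministic across subjects, runs and preprocessing arms. A
region with no contributing voxels raises an error naming it — never a
silent fill. Tables round-trip through TSV at 12 significant digits.

## MLDA

The pooled within-class scatter is the *sum* of class-centered outer
products (not the average); eigenvalue flooring is scale-covariant either
way, but the convention is fixed for bit-reproducibility. Eigenvalues below
their mean are raised to the mean, which makes the scatter SPD whenever the
mean is positive — the whole point when p ≫ n. When all eigenvalues are
equal the floor is inactive and MLDA coincides exactly with classical LDA.
A discriminant score of exactly 0 is classified as HC (class 0), a fixed
documented tie-break. Whether the original formulation floored the scatter
or the covariance (scatter/n) is immaterial for the decision rule: the
floor commutes with the scaling.

## The fused pipeline

**Standardization protocol.** Default (`scaling="train"`): the z-scaler is
fit on the fold's training rows (sample SD, ddof = 1) and applied to the
held-out row — no leakage. A `scaling="pooled"` mode standardizes with
all-subject statistics instead; it exists because the protocol wording in
this literature ("training and test sets normalized respectively") is
ambiguous, and a one-row LOOCV test set cannot be standardized on its own.
Zero-variance features are dropped with a warning.

**Selection** is an equal-variance two-sample two-tailed t-test per feature,
computed on training rows only, keeping P ≤ threshold *inclusive*, per
modality block independently. An empty modality abstains: its base
classifier is skipped and the remaining voting weights renormalize to 1.
If all five blocks are empty, a direct fit raises; inside LOOCV such a fold
casts a zero vote score, which the tie rule maps to HC, and a threshold only
fails outright when every fold abstains. The accuracy permutation test maps
a wholly untrainable permuted cohort to the corresponding all-HC accuracy.

**Voting weights.** The literature never states how the voting weights are
set; this package uses each base classifier's training-set accuracy,
normalized to sum to 1 — the convention of the original multiclassifier
formulation. The vote score Σ w_m ŷ_m lies in [−1, 1] and doubles as the
continuous score for the ROC/AUC.

**Grid search.** LOOCV accuracy is evaluated at every threshold in
0.001…0.050 (step 0.001, 50 values); the argmax wins, ties broken toward
the smallest threshold (fewest features, deterministic). The threshold is
selected on the same LOOCV whose performance is reported — that reproduces
the published protocol faithfully and is, deliberately, an optimistically
biased estimate; on a null cohort the 50-threshold maximum sits visibly
above the per-threshold null accuracy for exactly this reason. The
implementation shares per-fold scalers and t statistics across thresholds
and caches MLDA fits per distinct selection set, so the full 50 × n-fold
scan on a 109 × 1230 table runs in seconds.

**Null behavior.** Under label exchange the fused vote is symmetric between
classes — it carries no prior toward the majority class — so null LOOCV
accuracy centers near 50% regardless of class imbalance, and leave-one-out
biases it slightly *below* chance (removing a subject tilts its own class's
training mean away from it). Fold predictions share training data, so the
run-to-run spread is wider than a binomial model suggests. The calibrated
null check is therefore the permutation p-value, not the raw null accuracy.

**Feature weights.** Per fold and base classifier: |coef| / max|coef| ×
voting weight on the selected features (0 elsewhere); averaged over all
folds; summed across modalities per region. The reported set is restricted
to regions whose feature appeared in *every* fold for at least one modality,
ranked by descending weight; the report table shows the full-sample t and P
per modality, masked as "NS" above the optimal threshold.

## Inference

**Permutation tests.** The accuracy test permutes the label multiset
("without replacement") and reruns the entire pipeline — scaling, selection
and fitting inside every fold — per permutation; the AUC test permutes the
score vector against fixed labels. The p-value is the plain
count(permuted ≥ observed)/n_perm estimator of the source protocol, which
can legitimately return 0; a (count+1)/(n_perm+1) estimator is available
(`estimator="count_plus_one"`) for users who prefer a never-zero p. The
"≥" comparison is the conservative reading; strict ">" is a flag.

**DeLong test** uses the fast placement-value formulation: per class,
V₁₀/V₀₁ placements via midranks, covariance S₁₀/m + S₀₁/n, z = Δauc/SE,
two-sided normal p. Identical score vectors (zero variance of the
difference) return z = 0, p = 1 by convention. The implementation matches R
pROC's `roc.test(..., method="delong")` to 10 decimal places on a frozen
toy and is antisymmetric under swapping the classifiers.

**Demographics.** Sex tables use the Pearson chi-square *without* Yates
continuity correction (the corrected statistic would differ from the
conventional reporting of such tables); age uses the pooled-variance
two-sample t from group summaries, df = n₁ + n₂ − 2, standard two-sided p.

## Synthetic data

The generator defines the test conditions. Feature tables are multivariate
normal per modality with exchangeable correlation ρ (one shared latent
factor per subject and modality; default ρ = 0.2, marginal SD 1), and a
planted (region, modality, d) triple shifts the patient group by d marginal
SDs — Cohen's d is the single effect parameter. Default cohort: 45 patients
/ 64 controls, 246 regions, five modalities (1230 features). Where the
source cohort's per-modality effect sizes are unknown, test effects use
d ≈ 0.8–1.5 on ~15 regions across 2–4 modalities each — large enough for
stable recovery at n ≈ 109, i.e. chosen for testability, not realism.

Image fixtures are small 4D grids (default 16×16×10 × 60 volumes,
TR = 2 s — the real acquisitions' 150-volume, TR 2000 ms design at reduced
scale) with a 1-voxel border mask, an atlas that tiles the mask
mirror-symmetrically, one sinusoidal signal per atlas label at configured
(frequency, amplitude), optional white noise, and motion parameters that are
smooth random walks rescaled to a peak amplitude. Demographics tables
moment-match group age mean/SD exactly by affine rescaling, so summary
statistics are deterministic.

What this does *not* emulate: hemodynamic response shapes, 1/f and
physiological noise spectra, spatial autocorrelation, scanner artifacts,
registration error, or site effects. Passing tests therefore establish the
correctness of the algorithms and the internal calibration of the
inference, not expected classification accuracy on real cohorts.

## Problem sizes and determinism

The test suite and the acceptance script run the full-scale protocol
(109 × 1230 grid search) directly, since the threshold-sharing
implementation keeps it at seconds; permutation checks use 200 permutations
on 40-subject, 100-feature null cohorts, and recovery checks use LOOCV at a
fixed P ≤ 0.01 (planted d = 1.5 features are selected with power ≈ 1
there, so rerunning the 50-point grid per repeat would not change the
ranking). Every stochastic step takes an explicit integer seed; identical
seed and configuration reproduce bit-identical tables, folds, permutations
and outputs. Multi-arm experiments derive per-arm and per-permutation seeds
deterministically from one root seed.

## Known limitations

- Voxelwise preprocessing upstream of the metrics (slice timing,
  realignment, segmentation, spatial normalization) is out of scope; inputs
  are assumed aligned to a common (symmetric, for VMHC) grid.
- Degree centrality builds the full in-mask correlation matrix — fine for
  the intended map sizes (≲ 10⁴ in-mask voxels), quadratic beyond.
- The grid search reports the protocol-faithful, optimistically biased
  accuracy; a nested tuning loop is deliberately not the default because
  fidelity to the published procedure is the point. Use the permutation
  test for honest significance.
- Power-264-style sphere parcellations must be supplied as volumetric label
  images; the package does not build spheres from coordinates.
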