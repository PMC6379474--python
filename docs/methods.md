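# Methods

This document records the statistical models, parameter conventions and
numerical choices implemented in `fcdens`, and the design and limits of the
synthetic data generator used to validate them.

## 1. Data model and geometry

Volumes live on a `VolumeGrid` — dimensions, isotropic-or-anisotropic voxel
size in mm, world origin.  Only scaled-translation affines are supported;
NIfTI files with rotational or reflective components raise
`UnsupportedOrientationError` rather than silently resampling.  A
`GrayMatterMask` fixes the analysis domain; voxels are enumerated in
lexicographic index order throughout, so all per-voxel vectors are aligned
by construction.

## 2. Preprocessing

Applied per subject, in order:

1. **Discard** the first 10 volumes (signal-equilibration convention for a
   240-volume, TR = 3 s acquisition → 230 analyzed volumes).
2. **Motion screen**: exclusion when any translation exceeds 1.5 mm or any
   rotation exceeds 1.5° (strict inequality; exactly 1.5 passes).  A
   failing subject aborts the study rather than being silently dropped —
   the sample is a study condition, not a tunable.
3. **Nuisance regression**: Friston-24 motion expansion (6 parameters,
   their one-volume lag, and both squared) plus mean white-matter and CSF
   signals where supplied; an intercept is always included.  The design is
   QR-checked; rank deficiency raises `DesignError` naming the offending
   columns.
4. **Linear detrend** (least-squares line removal).
5. **Band-pass 0.01–0.1 Hz**.  Default is a zero-phase DFT-bin filter:
   coefficients with `band_low ≤ f ≤ band_high` are kept, all others
   zeroed.  This is exact in-band/out-of-band at bin frequencies and has no
   edge transients, at the cost of implicit periodicity; a Butterworth
   `sosfiltfilt` option exists (`filter_method="butter"`).  Bands at or
   above Nyquist (1/6 Hz at TR = 3 s) are rejected.

## 3. Functional connectivity density

For voxel *i*, the **global FCD** is the number of mask voxels *j ≠ i* with
Pearson `r(i, j) > r_threshold` (strict).  **Short-range FCD** restricts
*j* to voxels within 6 mm center-to-center (inclusive — on a 3 mm grid
that is the 32-voxel neighborhood); **long-range FCD** is the remainder, so
short + long = global identically.  No connectedness/region-growing
constraint is applied to the short-range count; the 6 mm ball is the
definition.

The computation is exact, not approximate: time series are z-normalized
once, correlations are computed in column blocks (default 512) as scaled
dot products, and counts accumulated.  Constant time series (zero variance)
correlate with nothing and emit a `RuntimeWarning`.  Equivalence with the
dense `corrcoef` brute force is enforced in the test suite for every block
size and threshold.

Thresholds: the adopted analysis threshold is `r = 0.45`; the robustness
sweep covers `{0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.60, 0.75}`.

**Normalization**: each subject's map is divided by its mask mean
("mean-scale", mask mean → 1), the convention for FCD group comparisons; a
z-score option exists.  An all-zero map (possible for the long-range count
at very strict thresholds in small synthetic grids) cannot be mean-scaled;
the study model substitutes a zero map with a `RuntimeWarning` so the sweep
continues, while `mean_scale` itself keeps the strict error contract.

**Smoothing**: 6 mm FWHM Gaussian, mask-weighted (numerator and denominator
smoothed separately, ratio taken inside the mask) so signal does not bleed
across the mask boundary and a constant map stays constant.

## 4. Group inference

- **Within-group**: voxel-wise one-sample t against zero on the normalized
  maps, Benjamini–Hochberg FDR at `q = 0.001` (the study model's default;
  `q` is a parameter — see the decisions ledger on this ambiguity).
- **Between-group**: voxel-wise OLS of map value on
  `[intercept, group, age, education]`, patient coded 1, so positive t
  means patients higher.  With no covariates this reduces exactly to the
  pooled-variance two-sample t (tested to 1e-10).  Constant covariates are
  dropped (absorbed by the intercept); a design made rank-deficient by a
  group-confounded covariate raises.
- **Summary-statistic t**: `t_from_summary` implements the pooled-variance
  t from per-group mean ± sd, used for demographic tables.

**Residual smoothness** is estimated from the GLM residuals with the
classic gradient estimator: standardize each residual map over the mask,
compute the mean squared difference of neighboring voxels along each axis,
set `λ = E[diff²]/Δ²` and `FWHM = √(4 ln 2 / λ)`.  White noise gives
`√(2 ln 2) ≈ 1.18` voxel widths; smoothing kernels add approximately in
quadrature.  Axes without neighbor pairs in the mask are non-estimable
(NaN); the study model averages the finite values over axes and map kinds.

**Cluster correction** is an AlphaSim-style Monte Carlo: Gaussian white
noise on the mask's grid, smoothed to the estimated FWHM, re-standardized
within the mask, thresholded at the two-tailed voxel `p = 0.01`, maximum
suprathreshold cluster size recorded per iteration (maximum over both
signs, matching the two-tailed analysis).  The extent threshold is the
smallest `k` with `P(max ≥ k) ≤ 0.05`.  Default connectivity is 26-connected
("corners"), 1000 iterations (300 in desk-scale tests).  The classical
volume criterion is also exposed: 1080 mm³ at 3 mm voxels ↔ 40 voxels.
Clusters are extracted per sign above the two-tailed voxel threshold,
filtered by extent, and reported with peak t and world-mm peak location.

## 5. Discrimination and correlations

Per corrected cluster, the subject-level **region value** is the mean
normalized map value over cluster voxels.  ROC analysis uses the midrank
Mann–Whitney AUC (ties at half weight), reported oriented so AUC ≥ 0.5 with
the direction recorded.  The **cutoff** maximizes Youden's J over
thresholds midway between adjacent observed values (first maximum on ties);
sensitivity and specificity are the empirical class fractions at that
cutoff, hence multiples of 1/n per class.  All of this is in-sample, as in
the motivating study; no cross-validation is claimed.

The **combined score** over ≥ 2 regions orients each region so higher is
more patient-like (sign-flipping regions where patients score lower), then
averages — a "mean FCD signal value", not a fitted classifier.

**Clinical correlations** are Pearson r within the patient group, two-tailed
p from `t = r√((n−2)/(1−r²))` on n−2 degrees of freedom.  The printed pair
r = −0.513, n = 24 → p = 0.010 is reproduced by this transform.

## 6. Synthetic data generator

Each subject's masked BOLD is built from:

- a **spatially correlated noise field**: white Gaussian noise smoothed
  with a 3 mm FWHM kernel (face-neighbor correlation ≈ 0.25), then passed
  through a temporal AR(1) filter (φ = 0.3) and standardized per voxel.
  The spatial correlation gives control subjects a realistic nonzero
  background degree so mean-scale normalization is well-defined;
- **hub signals**: for each hub (a declared voxel set, validated to be
  genuinely short-range — all pairs ≤ 6 mm — or long-range — all pairs
  > 6 mm), member voxels mix a shared AR(1) latent signal with their own
  noise as `x = √ρ·s + √(1−ρ)·ε`, giving exact expected pairwise
  correlation ρ;
- **group effects**: patients multiply the shared-signal weight by `m`, so
  the patient within-hub correlation is `ρ·m²` (validated < 1);
- **subject jitter**: per-subject couplings get truncated Gaussian jitter
  (sd 0.03), creating the between-subject variability clinical correlations
  attach to;
- **clinical variables**: `y = r·z + √(1−r²)·e`, scaled to a target
  mean/sd, where `z` is the subject's hub coupling standardized *within
  each group* — so the designed correlation holds inside the patient group
  instead of being swamped by the between-group coupling gap.

The reference configuration (`reference_config`) injects one short-range
"plus"-shaped hub whose coupling rises in patients (0.05 → 0.80) and one
long-range 8-corner-cube hub whose coupling falls (0.81 → 0.073), on a 12³
desk grid with 6 + 6 subjects (scalable to 24 + 24 on 16³).

**Realism and limits.**  The generator reproduces the statistical structure
the pipeline is sensitive to — spatial and temporal autocorrelation, graded
within-hub coupling, group-modulated degree, designed clinical coupling —
but not anatomy: no gray/white contrast, no physiological noise spectra, no
motion artifacts (motion screening is validated on constructed confound
tables instead), and hub geometry is idealized.  Recovery claims are
therefore about the pipeline's statistical behavior, not about anatomical
localization.

**Ground truth for recovery scoring** is the hub mask dilated by the 6 mm
smoothing FWHM: with strong injected effects the corrected cluster
necessarily covers the kernel support around the hub, so the undilated
mask would penalize correct detections.  Dice ≥ 0.5 against this target
across seeds is the recovery criterion.

## 7. Determinism and numerical conventions

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; the Monte-Carlo extent simulation derives its
  stream from `SeedSequence([seed, constant])`.  Re-running a fit writes a
  byte-identical `report.json`.
- Strict inequalities: connection threshold (`r > thr`), motion screen
  (`> 1.5`), voxel threshold (`|t| > t_crit`).  Inclusive: 6 mm
  neighborhood radius (`d ≤ 6 mm`).
- Standard numerics are delegated: FFT filtering and `sosfiltfilt` (scipy),
  BH-FDR (`statsmodels.multipletests`), component labeling
  (`scipy.ndimage.label`), NIfTI I/O (nibabel).  The FCD degree
  computation, the smoothness estimator, the Monte-Carlo extent threshold
  and the ROC/Youden machinery are implemented here and validated against
  brute-force oracles and analytic values in the test suite.

## 8. Threshold-robustness caveat

`FcdStudyResults.threshold_robustness()` reports the Dice overlap of
corrected-cluster masks at each sweep threshold against the adopted
`r = 0.45`.  On the reference synthetic configuration the short-range
result is moderately stable across adjacent thresholds, but the long-range
result degrades quickly at lenient thresholds: background long-range degree
(the whole mask is a candidate neighbor) swamps the injected effect below
`r ≈ 0.35` on a 12³ grid.  This is a property of the small synthetic world,
not of the method; the robustness table is reported honestly rather than
smoothed over.
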