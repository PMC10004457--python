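# Methods

`locrad` implements a two-level first-order radiomic analysis for
discriminating locally recurrent rectal cancer (LRRC) from post-treatment
scar in masked CT (Hounsfield units) and FDG-PET (SUV) lesion volumes,
together with a synthetic phantom generator that makes the whole pipeline
testable without patient data.

## Local parametric maps

For every in-ROI voxel a square 2D window is centred on it within its own
slice, and 12 first-order statistics of the window values are recorded,
giving 12 parametric maps defined exactly on the ROI support:

mean (Mn), median (M), excess kurtosis (K), skewness (S), histogram
entropy (E, bits), histogram uniformity (U), interquartile range (IQR),
coefficient of variation (CV), standard deviation (SD), median absolute
deviation (MAD), and the mean (Mn90th) and median (M90th) of the last
decile (values at or above the 90th percentile).

The window's pixel side is the smallest odd integer whose physical extent
covers a fixed side length — 5 mm for CT and 10 mm for PET — with a floor
of 3 pixels (a 3x3 neighbourhood being the smallest window on which local
dispersion is meaningful; the floor engages only when the in-plane pixel
pitch exceeds roughly half the physical side). Windows are 2D because the
axial pitch of clinical protocols (2-5 mm CT, ~3.3 mm PET) precludes
isotropic 3D neighbourhoods; the third dimension enters at aggregation.

Numerical conventions, frozen so that oracles and engine agree bit for bit:

* quantiles: linear interpolation between order statistics (type 7);
* skewness m3/m2^1.5 and excess kurtosis m4/m2^2 - 3 with population
  (1/n) moments; both defined as 0 when m2 = 0; SD uses the n-1 divisor
  (0 for a single sample);
* entropy/uniformity: 16 equal-width bins spanning the ROI-wide min-max
  of the source volume, shared by all windows of a sample. Tiny windows
  (9-81 voxels) cannot support per-window adaptive binning; a shared,
  shift-covariant span keeps the maps covariant under intensity shifts.
  Values outside the span (possible for windows overlapping the ROI
  exterior) clip into the edge bins;
* CV = SD/|mean|, reported as 0 when |mean| <= 1e-6 x the histogram span
  (CT windows can straddle 0 HU);
* windows are truncated at image borders, never padded, and by default
  keep every image voxel they cover (window centres must be in-ROI;
  `clip_to_roi=True` restricts the window to ROI voxels).

The engine groups equal-shaped windows and evaluates them as vectorised
batches; each batch row is reduced independently, so the result equals a
naive per-voxel loop exactly (asserted bit-for-bit in the tests on
multi-slice fixtures with border truncation).

## Aggregation to 144 features

Each map's in-ROI values are pooled across all slices into one
distribution and summarised with the same 12 statistics (the
entropy/uniformity histogram now spans the pooled map's own min-max, 16
bins). The 12 x 12 = 144 features are keyed `"<MAP>-<STAT>"`; e.g.
`S-MAD` is the median absolute deviation of the local-skewness map and
`K-M90th` the median of the last decile of the local-kurtosis map. The
codes Mn/M keep mean and median unambiguous while reproducing the names
used in clinical reports (S-MAD, K-M90th, U-CV, M-CV, E-IQR, M-IQR).

## Discrimination study

Given a cohort table (samples x 144, LRRC the positive class):

1. **Standardization** — each feature is z-scored across all samples
   pooled (n-1 SD); zero-dispersion features are dropped with a warning.
2. **LASSO screening** — an L1-penalized binomial model is fitted over a
   60-point descending penalty path (liblinear), with each sample
   weighted by its class's empirical prior probability n_c/N (the
   literal reading of prior weighting, which up-weights the majority
   class; `inverse_prior` and `none` are one flag away). The penalty is
   chosen by stratified 5-fold cross-validation at the minimum mean
   weighted binomial deviance; the intercept-only model is an explicit
   path candidate, so uninformative data yield an empty selection (ties
   resolve toward the sparser model). Features with nonzero coefficients
   in the full-data refit are selected.
3. **Univariate ranking** — for each selected feature: two-sided
   Wilcoxon rank-sum p (exact enumeration when both groups have <= 10
   members and the pooled values are tie-free, otherwise the normal
   approximation with tie and continuity correction), Holm-Bonferroni
   adjustment over the selected set, per-group variances (standardized
   units), the empirical ROC with AUC computed by the rank
   (Mann-Whitney) identity (ties count 1/2; orientation fixed with
   higher values scoring toward LRRC, AUC < 0.5 reported as-is), a
   stratified percentile-bootstrap 95% CI (2000 replicates, seeded), and
   the Youden-optimal operating point (ties broken toward higher
   specificity) with informedness I = SN + SP - 1 computed literally
   from the reported SN and SP.

If the selection is empty the univariate stage runs on all features and
the report is flagged; the Holm family is then the full feature set,
which is conservative. Reports always carry raw and adjusted p-values,
the seed, fold count, weighting mode, bootstrap settings and a config
hash, and serialize to JSON deterministically.

The bootstrap CI and the Youden operating-point rule are the package's
choices: the corresponding clinical reports print CIs and SN/SP pairs
without stating their methods, so both choices are flagged in every
report rather than silently assumed.

## Phantom generator

No imaging is distributable for this clinical problem, so the generator
emulates the structure the analysis assumes. Each sample is an
ellipsoidal ROI (random axis ratios, log-normal volume with median
25.31 cm^3 for CT / 9.32 cm^3 for PET, log-SD 1.1, clipped to the
reported cohort ranges 0.45-531.43 / 0.98-189.97 cm^3) inside a padded
grid at (2.0, 0.7, 0.7) mm CT or (3.3, 3.3, 3.3) mm PET spacing, with
values in a 20-180 HU or 1-15 SUV window.

Both groups share: a lesion-vs-background intensity offset, a smooth
Gaussian-filtered bias field (8 mm correlation length, SD 18% of the
value window), homogeneous voxel noise (SD 8% of the window), and sparse
signed intensity spikes (0.4-0.8% of ROI voxels per sample, amplitude
>= 4 noise SDs) that emulate reconstruction artifacts/speckle. The spike
rate varies between samples in both groups, which makes tail-sensitive
summaries of any parametric map (SD, last-decile statistics) noisy — a
deliberate nuisance dimension that rewards robust aggregations, the same
argument that favours MAD-based features on clinical data.

Recurrence (LRRC) samples additionally partition the ROI into Voronoi
blobs around uniformly drawn in-ROI centres (5-15 drawn, capped so each
blob is at least about two analysis windows across — finer partitions
are invisible to the window-scale analysis). Each blob perturbs the
shared texture with mechanisms that are mean-centred within the sample,
so only the *spatial dispersion* of local statistics distinguishes the
groups, not sample-level first-order shifts:

* a zero-sum per-blob mean offset (SD 4% of the window per unit effect)
  — disperses the local median/mean maps (M-CV, M-IQR);
* a log-centred per-blob noise-scale multiplier (log-SD 0.08 per unit
  effect) — disperses the local SD/entropy/uniformity maps (U-CV,
  E-IQR);
* per-blob skewed noise: standardized gamma draws with identical mean
  and variance but target skewness of magnitude 0.2-0.5 per unit effect,
  direction alternating between blobs — so a lesion mixes regions of
  mostly-higher with regions of mostly-lower local values, dispersing
  the local skewness and kurtosis maps (S-MAD, K-M90th).

A single `effect` parameter scales all three mechanisms; at `effect=0`
every perturbation vanishes identically and both groups draw from the
same process, giving exact null cohorts. All draws derive from one seed
per sample, recorded in the cohort provenance.

What the phantoms do not emulate: pelvic anatomy, scanner point-spread
and reconstruction noise correlations, partial-volume effects at the
lesion rim beyond the simple intensity step, SUV calibration error, and
inter-scanner batch effects. Passing the packaged studies therefore
shows that the *pipeline* recovers window-scale heterogeneity planted at
clinically calibrated lesion sizes — not that real LRRC tissue has this
texture.

## Validation studies and problem sizes

The packaged studies (`locrad.studies`, exercised by the test suite and
`scripts/acceptance.py`) use problem sizes chosen to keep a full run on
one CPU in minutes:

* volume calibration: 200 draws per modality at native geometry in the
  test suite; the validation script reports the median over 2000
  mask-only draws, since the 200-draw median of a log-SD-1.1 log-normal
  still carries ~10% sampling noise;
* null calibration: 100 effect-zero PET cohorts at the clinical arm
  sizes (33 vs 24); familywise error is the fraction of cohorts with any
  Holm-significant feature. Measured rates are near-nominal (3-14% over
  100-cohort batches, 5% over a 200-cohort batch), because the
  minimum-CV-error rule prefers the intercept-only model on ~90% of null
  cohorts and the occasional non-empty selections carry the residual
  selection bias;
* signal recovery and effect monotonicity: 20 cohorts of 30 vs 30 per
  effect on a CT-like geometry with coarsened in-plane sampling
  (2.0, 1.4, 1.4) mm. The adaptive window rule gives 5-pixel windows
  there, preserving the window-to-lesion scale relation of the native
  CT protocol at tractable cost (native-resolution cohorts are ~20x
  slower and add nothing to the property being checked). The documented
  "strong" effect for recovery is 2.5.

PET-geometry lesions at the reported median volume (9.32 cm^3 is ~260
voxels at 3.3 mm pitch, two to three 10-mm windows across) are largely
below the scale at which window-level heterogeneity can be expressed,
and the PET studies here are correspondingly harder; the clinical
finding that PET AUCs (0.67-0.70) trail CT AUCs (0.76-0.82) is
consistent with this geometry argument.

## Known limitations

* The LASSO stage selects one representative from each block of highly
  correlated features; which dispersion statistic of a given map
  survives is decided by small margins. The generator's spike nuisance
  makes S-MAD the systematic representative of the skew-dispersion
  block, but occasional swaps to sibling features (S-M90th, S-SD)
  remain.
* Holm correction is applied over the selected set only (matching the
  reported clinical p-values); familywise error control on null data
  therefore rests on the minimum-CV-error rule usually preferring the
  intercept-only model. The packaged null study measures this directly.
* The fractional-SUVmax ROI proposal implements only the reproducible
  thresholding step; expert correction of contours is not computable.
* Window anisotropy: the pixel side is derived from the mean in-plane
  pitch; strongly anisotropic in-plane grids would make the physical
  window rectangular.
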