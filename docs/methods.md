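# Methods

This note records the models implemented in `gliomics`, the parameter
defaults and why they were chosen, the numerical edge-case handling, and
what the synthetic phantoms do and do not demonstrate.

## Inputs and regions

Volumes are 3D NIfTI in the BraTS convention: four co-registered,
skull-stripped modalities (T1, T1Gd, T2, FLAIR) with zero background, and
an integer label map over {0 background, 1 necrosis/non-enhancing, 2 edema,
4 enhancing}. Voxel indices are 0-based; axis 2 is the axial (slice) axis.
Label 1 is treated as "necrosis" throughout (BraTS merges necrotic and
non-enhancing tissue under one code). The brain mask — the denominator of
all "/brain" volume ratios — is the nonzero-T1 support cleaned to its
largest connected component; inputs are assumed preprocessed, so no
registration, bias correction or skull stripping is performed. The brain
definition is a package decision: no single convention exists for it, and
ratios change by a few percent under alternatives (e.g., union of all
modality supports).

## Texture representations

All windowed operators run slice-wise on axial slices with reflect padding
and are computed inside the whole-tumor bounding box (margin 4 voxels), the
only place their statistics are consumed.

**PTPSA fractal dimension.** For each pixel's `window × window`
neighborhood (default 9) and each scale `s ∈ {1, 2, 4}` (each must divide
window−1), the neighborhood is tiled into s×s cells; a cell's four corner
intensities plus their mean at the cell center span four triangles of a
prism, and the areas sum to A(s). The fractal dimension is
FD = 2 − slope of log A(s) vs log s (ordinary least squares), clamped to
[2, 3]. A flat surface gives A(s) = const, slope 0, FD = 2 exactly — this
is an exact identity, not an approximation, and is asserted in the tests.
Window 9 with scales {1,2,4} keeps three points on the regression line at
desk-scale cost; larger windows smooth the map without changing its
ordering on rough-vs-smooth inputs.

**mBm Hurst map.** The local Hurst exponent of a multifractional Brownian
surface is estimated from increment-variance scaling: for lag s, the mean
of squared centered differences (averaged over the two axes) is smoothed
over the pixel's window, and H = slope/2 of log E|ΔI|² vs log(2s) over
s ∈ {1, 2, 4}, clamped to [0, 1]. Zero-variance windows are reported as
H = 1 (the smoothest value) and flagged in the map's `degenerate` array
rather than producing −∞ logs. On 128² spectral-synthesis fractional fields
the estimator recovers H ∈ {0.3, 0.5, 0.7} with bias ≤ 0.1 (50 replicates);
the residual bias is the usual discretization effect of small lags.

**Hölder exponent.** α(x) = slope of log osc_r(x) vs log r with
osc_r = max − min intensity within Chebyshev radius r ∈ {1, 2, 3, 4},
clamped to [0, 1]; locally constant pixels report α = 1. A linear ramp
gives α = 1 (osc ∝ r); a step edge gives α = 0 at the edge (oscillation is
scale-invariant) — both exact.

**Textons.** Filter bank: 2 Gaussians (σ = 1, 2), 2 Laplacians-of-Gaussian
(σ = 1, 2), 6 oriented even bars (second Gaussian derivative, σ = 1.5,
elongation 3, orientations k·30°), all 13×13. Zero-mean (band-pass)
responses are rectified and locally averaged (5×5 energy pooling) so
textons encode texture energy rather than phase — without this, an
oscillating texture splits into anti-phase and zero-crossing clusters.
Channels are standardized over the fitting sample (so raw-intensity
channels do not drown the band-pass ones), then clustered with k-means
(K = 16, fixed seed 17, deterministic). Per-region texton histograms are
normalized to sum 1; k-means centers are fit on a subsample of up to
20,000 in-brain voxels for speed, with assignment over the full crop.

**Texture feature block.** The texture family is config-driven:
representations × modalities × regions × statistics, default
{raw, ptpsa, mbm, holder} × 4 × {WT, edema, ET, necrosis} × {mean,
variance, skewness, kurtosis, energy, entropy} = 384 scalars, plus 16-bin
texton histograms × 4 modalities × 4 regions = 256. The exact composition
of a texture block is not canonical in the radiomics literature; the schema
is therefore enumerable (`features.schema_report`) and logged with every
run rather than hard-coded.

## Shape, histogram and histogram-graph features

* **13 volume features** (mm³ via voxel spacing): V(WT); V(WT)/V(brain);
  each subregion over WT and over brain; ET and necrosis over edema;
  V(edema)+V(ET); V(edema)/(V(ET)+V(nec)); V(nec)/(V(edema)+V(ET)).
  Ratios with empty denominators are NaN (flagged missing), never ∞ or a
  silent 0, so the schema length is invariant.
* **27 area features**: 9 properties (area, centroid, perimeter,
  major/minor axis length, eccentricity, orientation, solidity, extent) of
  the whole-tumor silhouette — the logical-OR projection along each of the
  three axes — measured on the largest connected component via
  `skimage.measure.regionprops`. Centroid is reduced to one scalar (its
  distance from the projection-plane center, mm) so the property count is
  exactly nine. Projections, not central slices, are used: the silhouette
  of the whole tumor is what the three "viewpoints" see.
* **9 location/extent features**: per-axis WT centroid offset from the
  brain centroid, bounding-box extent, and coordinate spread (std), in mm.
* **Histogram statistics** (6 per tissue per modality over edema/ET/
  necrosis): mean, variance, skewness, kurtosis of the raw intensities;
  energy Σp² and entropy −Σp log₂p of the 64-bin normalized histogram.
  Regions with < 2 values or zero spread flag the higher moments as NaN.
* **832 histogram-graph features**: per (modality, region ∈ {WT, edema,
  ET, necrosis}): bin frequencies at 11, 15 and 23 bins spanning the
  region's min–max intensity, plus the argmax bin per binning
  (11+15+23+3 = 52; 52 × 16 = 832). Per-region min–max ranges make the
  features contrast-invariant per region; a global-range variant would
  couple regions and is intentionally not the default. Empty regions emit
  52 NaNs, preserving the count.

## Euler-characteristic features

χ of a 2D binary mask is V − E + F on the closed cubical complex of its
foreground pixels (pixels are faces; adjacent pixels share edges;
corner-touching pixels share vertices). This realizes the standard
complementary adjacency pair — 8-connected foreground, 4-connected holes —
and equals components minus holes, which the tests verify against an
independent labeling-based oracle on hundreds of random masks.

The directional Euler vector interprets "100 points at 72 angles" as an
Euler-characteristic-transform-style descriptor: for each direction
θ_k = 5k° (origin at the +x image axis), the height h(p) = p·u(θ) over the
region's pixels is thresholded at 100 evenly spaced levels between its
per-slice min and max, and entry (k, j) is χ of the sublevel set
{h ≤ t_j}. Min–max normalization per slice and region makes the vector
translation-invariant; a global normalization is available as a flag.
Implementation note: because a face/edge/vertex enters the sublevel complex
exactly when the minimum height over its incident pixels crosses the
threshold, an entire 72×100 matrix reduces to three sorted-array rank
lookups per angle — no per-threshold labeling.

Per-slice matrices are summed over all axial slices of a region and
flattened angle-major to length 7200; a subject carries four such vectors
(WT, edema, ET, necrosis). An empty region yields the zero vector.

One caveat found during verification: the sublevel sets of a *digital*
convex region are not always connected — at oblique angles two boundary
pixels can tie at near-minimal height without being 8-adjacent, so a row of
the matrix can briefly read χ = 2 even for a disk. The brute-force oracle
agrees; this is a property of digitization, not an implementation error.

## Label fusion and Dice

Fusion unions per-class masks of two segmentations; a voxel claimed by
different classes resolves by ET > necrosis > edema (the most specific
tissue wins, preserving the WT ⊇ TC ⊇ ET evaluation hierarchy). Union
fusion can only add positives, so per-region sensitivity against any
reference is ≥ the max of the inputs' sensitivities — asserted as a
property test. DSC of two empty masks is defined as 1.0 (the common BraTS
tooling convention). A soft Dice loss
1 − 2Σpg/(Σp² + Σg²) is provided as a reusable objective; training
segmentation networks is out of scope, and the fusion operation accepts any
two label maps, so deep-segmenter outputs are an interchangeable input.

## Survival pipelines

Risk classes use 30-day months: short < 300 days, medium 300–450 (both
boundaries inclusive, i.e., day 300 and day 450 are medium), long > 450.
The month→day convention is a package decision; the class definitions are
stated in months while survival is recorded in days.

**Univariate Cox screening** uses lifelines' partial-likelihood Newton fit
(Breslow ties), reporting the coefficient, SE, and Wald p. Two guards:
non-convergence is retried with a small ridge penalty (0.1) and flagged;
and when the partial likelihood is monotone (e.g., a dichotomized perfect
predictor completely separates survival), the Wald SE explodes and its p
tends to 1 (Hauck–Donner), so the likelihood-ratio p is reported instead
whenever |β| > 10 or SE > 50|β|. Calibration: on null features the p < 0.05
rate is 0.05 ± 0.02 (simulation in the test suite).

**SP1 selection** is a three-stage AND: continuous Cox p < 0.05; Cox on
the median-dichotomized copy (≥ median → 1) p < 0.05; median-split
log-rank p < 0.05. The last step operationalizes "splits the cohort into
long vs short survival" as a two-group log-rank test, the standard choice
for a binary split. The three-stage AND drives the null selection rate far
below the nominal 5%.

**SP2 selection (RFS)** is recursive feature elimination: fit an XGBoost
classifier, drop the lowest-importance 10% of surviving features, score
each subset by stratified 5-fold CV accuracy, return the best subset (ties
favor the smaller one); deterministic under a fixed seed. The Euler block
and the remaining features are processed independently and concatenated.
The inner scoring model uses lighter boosting (60 rounds, learning rate
0.2) than the final model purely to keep the elimination loop fast; the
returned subset is always refit with the full settings.

**Models.** SP2: XGBoost with max_depth 3, 200 rounds, learning rate 0.1,
L1 = L2 = 1.0, fixed seed (no canonical hyperparameters exist for this
setting; these are conventional small-cohort defaults and are exposed in
config). SP1 variant: 200-tree random forest. Per-class day regressors are
XGBoost regressors whose features are Cox-screened (p < 0.05) within that
class's subjects — falling back to the single highest-variance feature if
nothing passes or the class has < 10 subjects — and whose predictions are
clamped to the class's day interval; classes with < 5 subjects are flagged
low-confidence. Prediction dispatches each subject to the regressor of its
predicted class. Modified SP2 scales importances so the maximum is 100%
and keeps features strictly above 50%, falling back to the top-1 feature
with a warning if the cut empties the set.

**Evaluation.** Leave-one-out CV for the classifier; per-class LOO for the
regressors; per-class RMSE/MSE/MAE with the combined MSE defined as the
sum of the three per-class MSEs. Confusion statistics are one-vs-rest on
the predictions × reference matrix: sensitivity = TP/column total,
specificity = TN/(other columns total), balanced accuracy = their mean,
PPV = TP/row total, NPV = TN/(TN+FN); all rounded to 3 decimals for report
parity. Feature selection runs **outside** the LOOCV loop by default —
this mirrors the common (optimistic) protocol for these pipelines — and a
strict nested mode (`nested_selection=True`) reruns the screen inside each
fold for leakage-free estimates. The label-permutation test in the suite
(LOOCV accuracy 1/3 ± 0.1 on permuted survival) guards the plumbing
against leakage even in the default mode. Kaplan–Meier stratification
splits at the feature mean, fits product-limit curves with Greenwood 95%
bands, and reports the two-group log-rank p.

Missing (NaN-flagged) features are median-imputed column-wise at model
entry; the imputation is part of the documented surface, not silent.

## Phantoms and synthetic cohorts

`generate_phantom_subject` builds a brain ellipsoid containing nested tumor
shells (necrosis ⊂ enhancing ⊂ edema, default radii 5/8/12 voxels in a 64³
grid) with modality-specific means (FLAIR-bright edema, T1Gd-bright rim,
dark core) plus Gaussian noise (σ = 2), returning exact per-region voxel
counts for oracle tests. The 64³ default keeps a full feature extraction
under ~3 s; BraTS-sized grids are a parameter, not a different code path.

`generate_cohort` emulates the survival setting: iid standard-normal
features of which the first 5 (of 100) each add 1.5 to the log hazard;
survival days follow log t = a + b(log U − r) with U ~ Exp(1) and risk
score r. The intercept and slope are calibrated so the empirical 300/450
cut-offs land at the target class-mix quantiles (default 65/42/56 of 163,
the structure of a typical training cohort) — class membership depends
only on the ranks of log U − r, so this calibration fixes the realized mix
without touching separability, which is governed solely by the effect
size. The generator returns the planted-feature names as a recovery key.
An exponential baseline with log-linear effects matches the Cox assumption
the screening stages test; optional censoring is uniform.

What the phantoms do **not** emulate: MRI physics (bias fields, partial
volume, Rician noise), non-ellipsoidal tumor geometry, spatially
correlated texture within tissues, and correlated clinical covariates.
Passing tests therefore demonstrate correctness of the feature definitions
and recoverability of planted effects under the stated model — not
real-data segmentation or prognostic performance, which require the actual
challenge volumes and are out of scope here.

## Numerical choices and limitations

* All log-log regressions use a shared eps (1e-12) floor before logs;
  degenerate inputs are flagged, not silently floored away.
* PTPSA ∈ [2,3], Hurst/Hölder ∈ [0,1] by clamping; ties in regionprops
  (e.g., eccentricity of a square) resolve to skimage's conventions.
* Texton clustering, RFS, and all model fits are deterministic under their
  seeds; the pipeline fans one root seed out per stage via CRC-tagged
  `SeedSequence`s.
* The end-to-end report is reproducible byte-for-byte under a fixed config
  and seed.
* LOOCV with boosted trees on 163 subjects costs ~30–60 s per report on a
  single CPU; the synthetic study sizes in the tests (150–163 subjects,
  100 features) were chosen as the smallest cohorts at which the
  statistical claims (calibration bands, recovery rates) are stable.
* Known limitation: the texture-block composition and several operational
  details of the upstream feature definitions (brain denominator,
  histogram ranges, "points" of the directional Euler descriptor) are not
  uniquely determined by the radiomics literature; each such choice is
  isolated behind one function and documented above, so an alternative
  reading is a one-function change.
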