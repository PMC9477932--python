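# Methods

`fetrad` implements a static amino-acid (FET) PET radiomics analysis for the
binary problem of separating true glioma progression (TP) from
treatment-related changes (TRC). This note documents the models and
procedures, the conventions chosen where the design was genuinely open, and
what the synthetic phantoms do and do not emulate.

## Quantification

**SUV.** Tissue activity (kBq/ml) is divided by the injected activity per
gram of body weight: `SUV = tissue / (injected_MBq / weight_kg)` (the
MBq/kg ratio equals kBq/g). A volume already flagged as SUV refuses a
second conversion.

**Harmonization.** Cross-scanner harmonization is a 3D Gaussian filter
whose size is quoted in mm. Filter sizes in PET practice are quoted as
FWHM, so the default interpretation of "2.5 mm" is FWHM (sigma =
2.5/2.355 mm per axis, scaled by the voxel spacing); a `sigma`
interpretation is available via the `kernel_interpretation` argument.
Borders are zero-padded, conserving total intensity up to boundary
truncation.

**Background.** The healthy-brain reference is the arithmetic mean SUV over
a user- or phantom-supplied region in the unaffected hemisphere. Automatic
placement exists only for phantoms (an ellipsoid mirrored through the
mid-sagittal grid plane); clinical placement is an anatomical judgement the
package does not attempt.

**Segmentation.** The lesion is contoured in 2D: the transversal slice of
the hottest voxel is selected (ties resolved to the lowest linear index for
reproducibility), and the contour is the 8-connected component of voxels
with SUV >= 1.6 x background that contains that voxel. 8-connectivity plus
the component restriction excludes disjoint supra-threshold islands,
matching a contour grown from the hottest voxel. "No voxel reaches the
threshold" is a valid *no-lesion* outcome, not an error. The transversal
axis defaults to the third array axis.

**TBR.** `TBR_max` and `TBR_mean` divide the lesion's maximum and mean SUV
by the background mean. Every returned summary satisfies
`TBR_max >= TBR_mean >= 1.6` by construction; both the segmentation voxel
set and the TBRs are invariant under global intensity scaling.

## Feature extraction

Features are computed in the segmented slice on the TBR scale
(SUV / background) by default, which makes the fixed discretization bin
width of **0.1** scanner-independent; binning is *absolute* (origin 0, bin
g covers [(g-1)·0.1, g·0.1)), so bins are comparable across subjects. A
min-anchored alternative and an SUV-scale mode are config options. No
spatial resampling is applied.

Five families:

1. **Fractal** — box-counting dimension of the lesion boundary and a
   differential box-counting (DBC) dimension of the intensity surface.
   Both regress log N(s) on log(1/s) over dyadic box sizes, dropping the
   coarsest scales with fewer than 4 occupied boxes (the count saturates
   there and flattens the slope). Degenerate ROIs (< 4 boundary pixels)
   take the fallback values 1.0 (smooth curve) / 2.0 (flat surface).
   On ROIs of a few dozen voxels these are reproducible heterogeneity
   indices, not converged dimensions.
2. **First order** — mean, SD, min, max, range, energy, (biased) skewness
   and excess kurtosis of the raw intensities; entropy (log2) and
   uniformity of the discretized histogram. Constant ROIs take the
   continuity limits (skewness = kurtosis = entropy = 0, uniformity = 1).
3. **Shape/size** — area (mm^2), marching-squares perimeter (mm),
   circularity 4·pi·A/P^2, and maximum diameter as the largest pairwise
   voxel-center distance (0 for a single voxel). The marching-squares
   perimeter is biased short for very small ROIs, so tiny lesions can show
   circularity slightly above 1.
4. **Texture** — GLCM, GLRLM and GLSZM, all 2D in the segmented slice
   because the segmentation itself is 2D: four in-plane directions at
   distance 1 for GLCM/GLRLM with features averaged over directions
   (directions with no in-ROI pair are skipped; if none has a pair the
   degenerate fallbacks apply), 8-connected zones for GLSZM. GLCMs are
   symmetrized and normalized per direction. Matrices are stored over the
   occupied gray levels with the actual level values attached; empty levels
   contribute nothing to any implemented feature. Implemented features:
   GLCM energy, contrast, correlation, homogeneity, joint entropy, IMC1,
   and **IMC2 = sqrt(1 - exp(-2 (HXY2 - HXY)))** with HXY the joint entropy
   and HXY2 the entropy of the marginal product (log2); GLRLM short/long-run
   emphasis, run-length and gray-level non-uniformity (both in normalized
   form, divided by the squared run count), run percentage; GLSZM
   **intensity non-uniformity normalized INN = sum_g (sum_z s(g,z))^2 / N_z^2**,
   zone-size non-uniformity normalized, small/large-zone emphasis, zone
   percentage. Single-level ROIs take continuity fallbacks (IMC1 = IMC2 =
   correlation = 0, entropies 0) rather than missing values.
5. **Wavelet** — a one-level 2D DWT (`db3`, compact 6-tap orthogonal
   kernel) of the lesion bounding-box patch into LL/LH/HL/HH, with the
   fractal (DBC), first-order and texture families recomputed per sub-band
   on mask-restricted coefficients. Boundary handling uses periodic
   extension ("periodization") so every sub-band is exactly half the patch
   size and aligns with a 2x block-OR decimated ROI mask. Sub-band
   coefficients are signed, so their discretization is min-anchored.
   Shape features are *not* recomputed: the mask is unchanged by intensity
   filtering, so they would duplicate the originals. Sub-bands with fewer
   than 2 in-mask coefficients return defined fallbacks plus a
   `*_degenerate` flag column.

The default inventory is 149 named features plus `tbr_mean`/`tbr_max`; the
name set and order are deterministic for a fixed config, and degeneracies
surface as documented fallback values, never as missing entries.

## Feature selection

Three stages, applied to the **training split only** (the stage functions
accept a single table, so validation/test labels are structurally out of
reach):

1. **Near-zero variance** — remove features whose most-common /
   second-most-common value ratio >= 19 *and* distinct-value fraction
   <= 10% (the common 95/5 + 10% convention), plus exact constants.
2. **Correlation** — while any pair reaches |Pearson r| >= 0.9, take the
   strongest pair and drop the member with the larger mean absolute
   correlation to all remaining features; ties break by name order.
   Pearson is the convention the 0.9 threshold belongs to; Spearman is not
   implemented.
3. **Forward selection under CV AUC** — greedy addition of the candidate
   maximizing the mean 5-fold stratified cross-validated AUC of an
   unpenalized logistic model, stopping when the best improvement is not
   strictly greater than 0.005. Fold assignment is seeded and shared across
   all candidate evaluations of a run. The inner fits use an in-package
   IRLS Newton solver (a vanishing 1e-8 ridge keeps the Hessian invertible
   under collinear folds; a coefficient cap at |beta| = 30 stops divergence
   under fold-level separation without affecting the ranking scores); the
   solver matches an sklearn logistic pipeline to the last retained feature
   on every table checked, at a fraction of the cost.

A caution documented by the verification suite: greedy forward selection
maximizes over ~p noisy CV-AUC estimates at every step, so on pure-noise
tables (n = 200, p = 20) it retains 3-5 features in roughly 40% of seeds
even with the 0.005 stop — the stop threshold bounds, but does not
eliminate, selection-induced optimism.

## Models and study design

Three unpenalized logistic models are fit on standardized training features
(train mean/SD; coefficients reported on both scales): *conventional*
(TBR_mean + TBR_max), *radiomics* (cascade-selected features), *combined*
(their union, refit jointly — stacking of model outputs was the alternative;
the joint refit is the simpler convention and keeps coefficients
interpretable). TBR_mean/TBR_max are excluded from the radiomics selection
pool; they define the conventional model. Complete separation is detected
and flagged, and only then a ridge (C = 1) fallback provides usable, flagged
coefficients. Subject-id overlap between splits raises a leakage error.

## Evaluation

The positive class is tumor progression; sensitivity is the
progression-detection rate. AUC uses the rank (Mann-Whitney) identity with
ties counting one half, which equals the trapezoidal area under the curve
to 1e-12. The decision cutoff maximizes sensitivity x specificity; among
ties the higher-specificity point wins (conservative against over-calling
progression). Test-set sensitivity/specificity are reported at the
validation-derived cutoff — the one available prospectively — with the
test-derived optimum also logged. The 95% AUC interval defaults to the
DeLong structural-components variance with a normal interval (clipped to
[0, 1]); a seeded stratified bootstrap (2000 reps, percentile) is the
alternative and the automatic fallback when the AUC is degenerate (0 or 1).
Group comparisons use the Mann-Whitney U test (exact enumeration when both
groups have <= 20 tie-free observations, tie-corrected normal approximation
otherwise) and Fisher's exact test for 2x2 tables (zero-margin tables
return p = 1 with a warning).

## Synthetic phantoms and cohorts

Patient scans are not available, so every end-to-end claim is made on
synthetic phantoms whose construction is: a constant background (default
1.0 SUV) with independent Gaussian voxel noise (default SD 0.05); an
ellipsoidal lesion (default 8 mm semi-axes on a 32x32x16 grid of 2 mm
voxels — desk-scale sizes chosen so a lesion slice holds ~50 voxels) whose
noise-free TBR is a plateau at the target TBR_mean plus a Gaussian random
field (smoothed white noise at a 4 mm correlation length, standardized
inside the lesion) scaled by the texture amplitude, clipped at the target
TBR_max, with the center voxel set to attain TBR_max exactly; and a
background ROI ellipsoid mirrored through the mid-sagittal plane. The truth
mask marks noise-free TBR >= 1.6. Per-subject parameters are drawn from
class distributions — the default development cohort uses 93 TP / 31 TRC
with TBR_mean 2.1±0.3 vs 1.9±0.3 and TBR_max 3.7±0.9 vs 2.8±0.7, and the
default test cohort 21 TP / 6 TRC with higher voxel noise plus the 2.5 mm
harmonization filter in the pipeline. Draws are truncated for validity
(TBR_mean >= 1.7, TBR_max >= TBR_mean + 0.2, amplitudes >= 0), which biases
planted means up slightly; the verification suite allows for this. Subject
seeds spawn deterministically from the master seed, so any subject is
reproducible in isolation.

No quantitative description of intra-lesion texture exists for either
class (the classes are visually indistinguishable), so the class texture
amplitudes are conventions, not estimates: TP 0.30±0.10 SUV, TRC
0.10±0.05 SUV (intra-lesion SD of roughly 15% vs 5% of a ~2 SUV lesion).
A side effect worth knowing: texture amplitude feeds back into the
*measured* TBRs (clipping, and threshold truncation of the contour), so a
class difference in amplitude alone lends some separation to the
conventional model too — the planted-effect control in the verification
suite therefore compares radiomics *against* conventional rather than
assuming conventional stays at chance.

What the phantoms do **not** emulate: anatomy, scanner point-spread
functions, scatter/randoms, partial-volume effects, dynamic uptake, or any
biological correlation structure between texture and TBR beyond the
mechanism above. Passing end-to-end tests therefore demonstrates that the
pipeline recovers the statistical structure it assumes — not clinical
performance on real scans.

## Verification problem sizes

The end-to-end negative control uses balanced 400-subject cohorts so the
3/1 split yields a 100-subject holdout (the null-AUC sampling SD at n = 100
is ~0.06, making the [0.35, 0.65] band a meaningful 2.6-sigma check; at a
25-subject holdout the band would be uninformative). The planted-effect
control uses 200-subject cohorts (50-subject holdout) and a 0.6 SUV TP
amplitude (intra-lesion SD ~30% of the lesion mean). Both run 50 fixed
seeds. Texture-oracle equivalence is exhaustive over all level patterns on
shapes up to 2x3 and randomized over 60 masked ROIs per larger shape.

## Known limitations

- 2D-only texture and shape analysis (by design, matching the 2D
  segmentation); a 3D mode would be an extension, not a correction.
- The feature inventory is an explicit, documented set covering the five
  families; it is not a reproduction of any proprietary toolbox inventory.
- DeLong intervals are slightly anticonservative at very small class
  counts; the bootstrap alternative is provided.
- Forward selection's null behavior (above) means selected features on
  small cohorts should be treated as hypotheses, not findings — which is
  also why the study design keeps a held-out validation split and an
  independent test cohort.
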