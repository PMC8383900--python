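# Methods

This note documents the models, numerical choices and limitations of
`fundtess`: what each stage assumes, which parameters matter, what the
synthetic generators do and do not emulate, and where the design was
genuinely open.

## The measurement chain

### ROI establishment

The imaged fundus field on a 45° photograph is a bright, near-circular
disc on a dark camera background, and the background is darkest in the
red channel. The ROI finder thresholds the red channel with Otsu's
method and keeps the bright side. Because the dark retinal-vessel tree
can cut the field into fragments at that threshold, the bright mask is
morphologically closed (square element, radius ≈ 2.5% of the short image
side) before connected-component labeling. Candidates are hole-filled
and screened by: mean red intensity at least the global mean, area at
least `roi_min_area_fraction` (default 0.15) of the frame, circularity
`4πA/P² ≥ roi_circularity_min` (default 0.6), and centroid inside the
central third of the frame. The largest survivor is the ROI; if none
survives, `NoROIFound` is raised and batch processing records the image
as skipped. On synthetic renderings spanning disc radii 0.30–0.45 of the
image side the recovered ROI overlaps the true disc at Jaccard ≥ 0.95.

### Denoising

Denoising is a per-channel frequency-domain low-pass: FFT, multiply by a
transfer function, inverse FFT, re-quantize to [0, 255]. The transfer
function is flat up to `lowpass_cutoff` × Nyquist and rolls off as a
Gaussian (width 0.1 × Nyquist) beyond it. Per-axis frequencies are
combined with the Chebyshev norm so that `lowpass_cutoff = 1.0` is an
*exact* pass-through — a plain radial Gaussian would attenuate even at
the unit cutoff. The default cutoff 0.35 suppresses most pixel noise
while preserving tessellation bands a few pixels wide. For any input
with spectral content above the cutoff, that high-band energy strictly
decreases.

### Lightness normalization

Brightness varies between photographs; the normalizer converts to
CIELAB and shifts the L channel so that its mean (over the ROI when one
is available) equals `target_L` = 60 on the 0–100 scale. A fixed target
— rather than a per-batch average — makes single images normalize
reproducibly. Saturated pixels clip against the sRGB gamut on the way
back, which drags the realized mean below the applied shift, so the
shift is iterated (up to 6 rounds, stopping inside ±0.25) instead of
applied once. A and B channels are untouched before the return
conversion.

### CLAHE enhancement

Contrast-limited adaptive histogram equalization is applied to the L
channel on a `clahe_tiles × clahe_tiles` grid with clip parameter
`clahe_clip` (in multiples of the uniform histogram bin height; default
2.0, mapped to scikit-image's fractional clip limit as `clahe_clip/256`).
Only ROI pixels are replaced; everything outside is bit-identical to the
input. The default grid is 4×4: tiles must stay large relative to the
tessellation bands, otherwise adaptive equalization treats dense
exposed choroid as the local background and suppresses the very signal
being measured. (8×8 is common for general photography but measurably
degraded the labeling stage at the package's working resolutions.) A
degenerate (constant-lightness) ROI is returned unchanged.

### Automatic labeling by channel subtraction

Exposed choroid is red-dominant relative to the overlying retina, so
the signed difference of two channels (default red − green) separates it
from retinal tissue. The difference image is smoothed with a Gaussian at
the band scale (σ = 1 px) to average pixel noise down, centered on its
ROI median (the retinal baseline), and thresholded at
`max(otsu, noise_floor)`. The fixed floor (default 25 intensity levels)
is what keeps a fundus *without* tessellation essentially unlabeled:
Otsu always splits a histogram somewhere, and every within-image scale
estimate we tried (MAD, one-sided quantiles, high-frequency residuals)
is either contaminated by the tessellation itself at high density or
inflated by CLAHE texture at zero density. A fixed floor is defensible
precisely because the preceding chain standardizes brightness (fixed L
target) and local contrast (fixed clip): the intensity scale is
comparable across images by construction. The thresholded mask is
optionally opened/closed (`morph_radius_px`, default 0) and components
below `min_blob_px` = 16 px are dropped; the result is intersected with
the ROI. On default-noise renderings the labeled density lands within
±0.05 of the rendered truth from ρ = 0.05 to 0.35 with Dice ≥ 0.6
(typically ≥ 0.8), and a tessellation-free rendering stays below 1% of
the ROI.

### Segmentation model

The learned stage is a compact fully-convolutional encoder–decoder
implemented directly in NumPy (im2col convolutions, manual backprop,
Adam): feature extraction at half resolution, nearest-neighbor
upsampling back to full resolution, and a 1×1 convolution producing
per-pixel logits. Two encoder depths are available — `tiny` (three 3×3
conv layers around one stride-2 stage; trains on 200 images of 128² in
about a minute on one CPU) and `resnet18` (the same layout with four
residual blocks). Training minimizes per-pixel binary cross-entropy
with the positive class up-weighted (`pos_weight` = 3) against the
foreground/background imbalance of tessellation masks; no augmentation.
Everything stochastic (weight init, batch shuffling) flows from
`SegModelSpec.seed`, so identical spec + data + seed reproduce identical
losses and weights, and inference is deterministic. Images are resized
to `input_size` (bilinear, anti-aliased) and normalized with fixed
constants; confidence maps are brought back to the input resolution by
nearest-neighbor resampling before thresholding at
`confidence_threshold` (default 0.5 — the natural operating point of a
probability map; nothing suggested tuning it). Checkpoints are a binary
weight archive plus a JSON sidecar recording the spec, loss history and
a SHA-256 digest of the training data.

### Density and performance metrics

`compute_ftd` counts pixels exactly: the choroid mask is intersected
with the ROI first (predictions cannot leak outside the imaged field),
`S1` and `S` are integers, and ρ is their exact quotient. `confusion`
restricts all four counts to ROI pixels; `metrics` computes accuracy,
sensitivity and specificity and raises `UndefinedMetric` naming the
metric whose denominator vanished, rather than returning NaN.

## The synthetic fundus renderer

The renderer emulates exactly the features the chain exploits, with
exact ground truth:

- a dark background and a red-dominant disc with radial shading,
- exposed choroid as *branching curvilinear bands* (random-walk trunks
  with occasional side branches, widths 2–5 px) of a more saturated
  red/orange hue — so channel subtraction faces realistic elongated
  structure rather than blobs,
- a darker retinal vessel tree drawn on top and *excluded* from the
  ground truth (vessels occlude choroid, as in real photographs),
- Gaussian pixel noise (default σ = 8 intensity levels) and a
  brightness gain.

Bands are added one at a time until the ground-truth density reaches the
target; the final band is truncated point-by-point (binary search over
its path) so the achieved density lands within ±0.01 of the target.
If the band budget (`n_choroid_vessels`) cannot reach the target,
`DensityUnreachable` is raised. Identical parameters and seed give
identical image bytes. The renderer does **not** attempt photorealism:
no optic disc, no parapapillary atrophy, no drusen or hemorrhages, no
camera vignetting or color profile, and its noise is white rather than
spatially correlated. Passing tests therefore demonstrate that the
chain's logic is correct on structurally faithful inputs, not that its
default thresholds transfer to any particular camera.

## The cohort generator and its calibration

The statistical half reruns an epidemiological analysis on a synthetic
population of elderly subjects (age ≥ 50). The generative model works on
the standardized scale:

1. A latent standard-normal 6-vector per subject carries the covariate
   correlation structure Σ.
2. Latents map to observed covariates: truncated normals for age
   (50–93 years, moments matched to 64.1 ± 9.7), parapapillary atrophy
   and SFCT (both left-truncated at 0); linear maps for BMI and axial
   length; sex by thresholding its latent at the 56.4% female split.
   The sex row of the latent correlation matrix is de-attenuated by
   κ = φ(τ)/√(p(1−p)) so the *observed* (binarized) correlations match
   Σ.
3. FTD = (standardized observed covariates) · β + Gaussian residual
   with variance 1 − R², rescaled to 0.14 ± 0.08 and clipped to [0, 1].
   Using the observed (post-truncation, post-binarization) columns in
   the linear predictor makes the regression recovery exact by
   construction; the clip at 0 (≈4% of mass) perturbs standardized
   coefficients by well under 1%.

**Why Σ must be solved, not assumed.** Independent covariates cannot
jointly reproduce the published per-covariate standardized coefficients
(β_SFCT = −0.58 dominating five smaller terms) and a multiple
correlation of R = 0.74 with a marginal age–FTD correlation of 0.33:
βᵀΣβ and (Σβ)ⱼ depend on the covariance. `calibrate_predictor_corr`
therefore solves a least-squares problem over the 15 free correlations
for a symmetric, unit-diagonal, positive-semidefinite Σ subject to:
βᵀΣβ = R² (±1e-3), each diagonal of Σ⁻¹ equal to its published variance
inflation factor (±0.05), (Σβ)_age = 0.33 (±0.02), and — a deliberate
addition — (Σβ)_axial ≈ 0.47. The last constraint exists because the
within-myopia SE–FTD correlation is structurally capped: selecting the
myopic stratum compresses the axial-length range (SD ≈ 0.55 of the
population SD), attenuating every axial-length-mediated correlation by
almost half; with a weaker axial-length–FTD link the −0.25 target is
unreachable by *any* refraction model. A weakly-weighted realism prior
(thinner choroid with age and elongation, etc.) selects among the
remaining degrees of freedom. The solve is deterministic and verified
after the fact; residuals outside tolerance raise `CalibrationFailed`.

**Refraction.** Spherical equivalent is generated from the axial-length
latent with a negative, heavy-left-tailed link: a lognormal myopization
term exp(μ + σ(c·z_AL + √(1−c²)·W)) plus a one-sided linear term in
max(z_AL, 0) and quarter-diopter rounding. The lognormal tail produces
the long myopic tail (population SE −0.13 ± 1.96 D but myopic-stratum
mean −2.16 ± 2.4 D) that no Gaussian can; the one-sided linear term
confines the axial-length signal to elongated eyes so the hyperopic
stratum stays nearly uncorrelated, as observed. Five link parameters are
calibrated by simulated least squares (fixed internal sample, so the
solve is deterministic) against: overall SE mean, myopia prevalence
(37.3%), myopic-stratum mean SE, the within-myopia SE–FTD correlation
(−0.25), and a near-zero hyperopic correlation. Cylinder is drawn small
and sphere is set so `se = sphere + cylinder/2` holds exactly in floating
point (all three live on dyadic grids).

Marginal means/SDs for BMI (25.3 ± 3.4 kg/m²), parapapillary atrophy
(1.5 ± 1.1 mm²) and SFCT (254 ± 107 µm) are field-realistic choices for
an elderly East-Asian population; every calibrated statistic is
location/scale-free, so these affect only the printed units.

**Analysis machinery.** Univariate screening fits one OLS per covariate
(raw B, standardized β, 95% CI, p). The stepwise multivariate model
first removes the highest-VIF predictor while any VIF exceeds 3, then
backward-eliminates the least significant predictor while any p exceeds
0.05, logging every removal; VIF is computed as 1/(1−R²ⱼ) from an
explicit regression of predictor j on the rest. Stratified summaries
use decade bins (50–59, 60–69, ≥70) with one-way ANOVA, a two-sample
t-test for sex, and the strict refraction partition (myopia SE < −0.25 D,
hypermetropia SE > +0.25 D, emmetropia otherwise — a boundary value of
exactly −0.25 D is emmetropic). Empty strata are reported with n = 0 and
missing statistics, never as exceptions. All p-values are two-sided.

What the cohort generator does *not* emulate: disease covariates
(glaucoma, AMD, vascular occlusion), measurement error in FTD itself,
survey nonresponse, or any causal structure — the correlations are
engineered, so recovery tests validate the estimation machinery, not an
epidemiological claim.

## Problem sizes and tolerances

The test suite and the acceptance script use: cohorts of n = 3074 (the
study's population size; moments of a single draw then fluctuate by
~0.02 on correlations, which is why correlation checks carry ±0.03
bands); 25 cohorts for coefficient recovery (mean β within 0.02,
CI coverage within [90%, 99%]); 100 cohorts for the backward-elimination
rate; and a segmentation benchmark of 240 rendered images at 128² (200
train / 40 held out, 10 epochs), sized so the full chain runs in about a
minute on one CPU while still training to pixel accuracy ≥ 0.97 and
sensitivity ≥ 0.97 at threshold 0.5.

## Known limitations

- The fixed `noise_floor` of the labeler presumes the package's own
  preprocessing; feeding raw, un-normalized images will shift its
  operating point.
- The NumPy network is intentionally small; it is a faithful,
  reproducible stand-alone implementation of the encoder–decoder idea,
  not a large-scale training framework. Checkpoint weights are
  platform-portable but bit-identical reproduction of *training* assumes
  one BLAS build.
- The renderer's band geometry is stylized; transfer of tuned defaults
  to clinical photographs requires recalibration on labeled data.
- The ±0.01 density control of the renderer is defined on the rendered
  mask *after* vessel occlusion, at the rendered resolution; heavy
  downstream resizing changes areas by more than that.
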