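# Methods

## Measurement model

A measurement is a triple (image volume, ROI mask, feature extractor).
Volumes are 3D scalar grids in Hounsfield units with anisotropic spacing
(dx, dy, dz) in mm, indexed (x, y, z); NIfTI-1 (nibabel) and NRRD
(SimpleITK) inputs are converted to this single internal convention on
read. Masks are binary volumes on the same grid — the copy-and-paste
semantics of ROI propagation only require grid-aligned masks, so no
contour rasterizer exists.

The study design the package reproduces: each lesion is measured under
three reconstruction variants of one acquisition (FBP-like, and two
iterative-like levels S3 and S5), by two readers, with reader 1 reading
twice — nine feature datasets per lesion. The ROI drawn on the FBP image
is propagated bit-identically to the other variants, so the
inter-reconstruction contrast is isolated from segmentation variability,
and every mask-only (shape) feature is exactly constant across variants.

## Feature definitions and conventions

Several conventions are undocumented in the wider literature and rescale
results, so they are explicit configuration recorded in output metadata:

| parameter | default | note |
|---|---|---|
| first-order histogram bins B | 256 | equal-width over the ROI's [min, max]; 8-bit convention |
| first-order entropy base | 2 (bits) | |
| skewness/kurtosis estimators | biased 1/n moments (g₁, g₂ excess) | excess makes a Gaussian score 0 and admits negative kurtosis |
| GLCM levels G | 256 | linear min–max quantization over in-mask voxels |
| GLCM distance / directions | 1 voxel / all 13 unique 3D directions pooled | rotation-robust single-matrix practice |
| GLCM entropy base | e (nats) | deliberately independent of the first-order base |
| GLCM "moments" | angular second moment Σp² | alternative `diff_moment2` selectable; the name is used inconsistently in the field, so the choice is explicit config |
| surface area method | isosurface mesh | exposed-voxel-face count kept as cross-check |
| CV aggregation across lesions | mean of per-lesion CVs | median selectable |
| CV denominator | absolute mean | keeps CVs finite and positive for sign-crossing features (HU mean, skewness) |

Degenerate inputs take explicit sentinels, not silent zeros: a constant
ROI has sd = 0, entropy = 0, homogeneity = 1, and NaN skewness/kurtosis;
a single-voxel mask has no co-occurring pairs (error) and undefined
discrete compactness (NaN with a warning); a feature identical across all
three algorithms for every lesion yields a `not_available` comparison
rather than a p-value, which is exactly what happens to shape features
under ROI propagation.

Surface area anti-aliases the padded binary mask with a Gaussian of
0.8 voxels before extracting the 0.5-level isosurface: the raw binary
staircase overestimates the area of a digital ball by ~8 % (sphericity
0.92 instead of ~1), while the anti-aliased mesh lands within 0.1 % of
4πr² at radius 20 voxels. For masks so small that smoothing erases the
0.5 level set the raw mask is used. Discrete compactness is defined on
6-connected voxel topology and deliberately ignores spacing anisotropy,
following the contact-area normalization's voxel-count formulation.

## Statistical pipeline

Per feature, the three algorithm groups (aligned per lesion) pass through
Shapiro–Wilk (α = 0.05 per group); if all look normal, a one-way
repeated-measures ANOVA (implemented in closed form; cross-checked
against statsmodels `AnovaRM` in the test suite) with Tukey HSD post-hoc;
otherwise Friedman with pairwise Wilcoxon signed-rank tests,
Bonferroni-corrected over the three pairs. Tukey carries its own
multiplicity adjustment, so the explicit Bonferroni factor applies to the
Wilcoxon branch only.

CV comparisons between variability sources are paired Wilcoxon
signed-rank tests on per-lesion CVs, with a Bonferroni family size of 4
by default (intra vs. inter reader, and inter-reader vs. each of the
three reconstruction pairs), giving the corrected threshold
0.05/4 ≈ 0.013. Per-lesion CVs that are NaN (undefined features) are
dropped pairwise before testing.

The type-I error of the full normality-gated ladder is simulated in the
acceptance suite: 1000 null replicates of 42 lesions with an additive
lesion effect and exchangeable algorithm columns reject at ≈ 0.05.

## Synthetic phantom study

The generator replaces unavailable patient scans and encodes the study
conditions as its defaults:

* **Geometry**: 0.68 × 0.68 × 1.00 mm voxels; lesion diameters drawn from
  a truncated normal (mean 22.6 mm, SD 8.5 mm, range 10.0–41.7 mm) with
  mild per-axis anisotropy, on a 96 × 96 × 64 grid.
* **Anatomy**: a lobulated ellipsoid (smooth random radial modulation,
  ±15 %) with a contrast-enhanced plateau (55 HU), an optional necrotic
  core, a smooth rim ramp toward −150 HU over the outer 30 % of the
  radius, and −800 HU lung background. A sparse 0.2 % of outer-shell
  voxels takes deep partial-volume values toward lung attenuation, as
  real tumor–lung interface voxels do. The plateau-plus-tail construction
  gives the left-skewed intra-tumoral histogram of solid enhancing
  nodules, and the deep boundary voxels anchor the in-mask intensity
  range so that min–max-calibrated features respond to noise through the
  bulk of the distribution rather than through range inflation.
* **Reconstruction emulation**: one correlated Gaussian noise field per
  acquisition (correlation length 0.5 mm — sharp-kernel CT noise is
  high-frequency), added at 60 HU SD for FBP and scaled by 0.60 (S3) and
  0.35 (S5). Sharing the realization across variants mirrors the fact
  that they reconstruct the same raw data, and makes the noise-level
  effect deterministic per phantom. Under these conditions in-mask SD,
  GLCM contrast and both entropies are ordered FBP > S3 > S5 and IDM the
  reverse, the directional effect the analysis is designed to detect.
* **Readers**: the signed Euclidean boundary distance (spacing-aware) is
  perturbed by a smooth random field (3 mm correlation) scaled to the
  reader's jitter amplitude and re-thresholded; the largest connected
  component is kept. Defaults: 0.3 mm for repeat reads by one reader,
  0.8 mm for a second reader — plausible manual-contouring wobble that
  makes inter-reader CV exceed intra-reader CV.
* **Cohort**: a 47-patient screening list with 4 patients lacking a
  measurable lesion and 1 ground-glass nodule, whose exclusion retains 42.

What the generator does **not** emulate: reconstruction-algorithm bias on
mean HU (noise is zero-mean, so the emulation cannot show the small mean
shifts real iterative reconstruction produces), beam hardening, dose
modulation, vessels/bronchi in the background, or sinogram-domain physics.
Passing tests therefore demonstrate the pipeline's statistical behavior
under a controlled noise-level contrast, not agreement with any absolute
feature magnitudes from patient data.

## Problem sizes and determinism

Tests and the acceptance script run phantoms on reduced grids
(64 × 64 × 48 or smaller, lesions 12–30 mm) — the feature mathematics is
grid-size independent, and these sizes keep the suites fast while leaving
thousands of in-mask voxels per lesion. The full study default remains
42 lesions at 96 × 96 × 64. All randomness flows from one seed through
`numpy.random.SeedSequence` spawning, so study reruns are byte-identical;
every output CSV embeds a SHA-256 hash of the configuration.

## Known limitations

* Absolute feature magnitudes depend on the binning/quantization
  conventions above; cross-software comparisons require matching them.
* The min–max adaptive quantization makes GLCM features dependent on
  in-mask range outliers; fixed-calibration quantization is not yet a
  config option.
* CV of features whose mean sits near zero is ill-posed; the absolute-mean
  convention bounds it but such CVs should be read qualitatively.
* Discrete compactness assumes 6-connectivity and isotropic topology;
  values for thin, plate-like lesions on anisotropic grids are not
  comparable across spacings.
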