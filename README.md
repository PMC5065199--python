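# ctradiomics

Reproducibility analysis of CT radiomic features for pulmonary tumors:
how much do quantitative imaging features move when the *reader* changes,
when the same reader repeats a segmentation, or when the CT scan is
reconstructed with a different algorithm (classical filtered back
projection vs. noise-reducing iterative reconstruction)?

The package is for imaging scientists who need to know which radiomic
features are robust enough to carry clinical meaning across reconstruction
settings, and it ships a synthetic phantom study so the full analysis runs
without patient data.

## What it computes

Fifteen features from a 3D tumor ROI on a Hounsfield-unit volume with
anisotropic voxel spacing:

* **First-order intensity** over the masked voxels *x*₁…*x*ₙ: mean, sample
  SD, skewness g₁ = m₃/m₂^{3/2}, excess kurtosis g₂ = m₄/m₂² − 3, and from
  an equal-width histogram *p*ᵢ over [min, max] (256 bins): entropy
  −Σ *p*ᵢ log₂ *p*ᵢ and homogeneity (uniformity) Σ *p*ᵢ².
* **Shape**, from the mask alone: volume *V* = *n*·dx·dy·dz, effective
  diameter (6*V*/π)^{1/3}, surface area of the anti-aliased 0.5-level
  isosurface mesh, sphericity π^{1/3}(6*V*)^{2/3}/SA, and Bribiesca
  discrete compactness (A_c − (n−1)) / (3(n − n^{2/3}) − (n−1)) with A_c
  the number of face-adjacent voxel pairs.
* **GLCM texture** on 256 gray levels, distance 1, the 13 unique 3D
  directions pooled into one symmetric matrix *p*(i,j): contrast
  Σ(i−j)²p, inverse difference moment Σp/(1+(i−j)²), entropy −Σp ln p,
  and angular second moment Σp².

Variability is quantified per lesion as the coefficient of variation,
CV = SD/|mean| × 100 %, over the repeated measurements that define a
source (repeat reads by one reader, two readers, or two reconstruction
algorithms with the identical propagated ROI), summarized across lesions
and categorized: very small (≤5 %), small (≤10 %), intermediate (≤20 %),
large (>20 %). Feature differences across the three reconstruction
variants are tested with a Shapiro–Wilk-gated ladder: repeated-measures
ANOVA with Tukey post-hoc when all groups look normal, otherwise Friedman
with Bonferroni-corrected pairwise Wilcoxon signed-rank tests.

Because one segmentation is copied unchanged onto every reconstruction
variant, shape features are bitwise identical across variants
(inter-reconstruction CV exactly 0), and the comparison test reports an
explicit not-available sentinel for them.

## Worked example

`examples/02_reconstruction_variants.py` builds one ~20 mm phantom,
emulates the three reconstruction variants from a single correlated noise
field (full amplitude for FBP, scaled by 0.60 and 0.35 for S3/S5),
propagates one ROI across them and prints:

```
feature                FBP         S3         S5
sd                  94.367     81.693     76.485
entropy              6.398      6.252      6.159
glcm_contrast      411.077    287.172    238.785
glcm_idm             0.067      0.087      0.108
glcm_entropy         8.565      8.225      7.983
volume            3958.606   3958.606   3958.606
sphericity           0.997      0.997      0.997
```

Noise-sensitive features fall monotonically as noise reduction strengthens
(IDM rises, being an inverse texture measure), while mask-only shape
features are exactly equal across variants — the core reproducibility
finding this pipeline quantifies. The other examples extract a single
feature vector (`01`) and run a small end-to-end variability study with
two simulated readers, printing the CV table by source (`03`).

A thin CLI wraps the same library calls:

```sh
ctradiomics run-all --seed 1 --outdir results/study
ctradiomics report --outdir results/study
```

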