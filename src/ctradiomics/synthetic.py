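"""Synthetic stand-ins for the study's patient scans.

Patient DICOM from the original cohort is not available, so this module
emulates the statistical structure of the study end-to-end:

* a lobulated ellipsoidal tumor phantom in lung-like background, with a
  contrast-enhanced plateau, an optional necrotic core, and a rim that ramps
  toward lung attenuation — giving the left-skewed intra-tumoral intensity
  histogram typical of solid enhancing nodules;
* matched reconstruction variants: one shared correlated noise field, added
  at full amplitude for the FBP-like image and scaled down for the two
  iterative-like images (S3, S5).  Sharing the realization mirrors the fact
  that the variants are reconstructions of the same acquisition and isolates
  the noise-reduction effect;
* imperfect reader segmentations: the ground-truth boundary displaced by a
  smooth random field of configurable amplitude (intra-reader repeat reads
  jitter less than a second reader);
* a screening cohort with exclusion flags (no measurable lesion,
  ground-glass nodule).

Everything is deterministic given the seeds carried in the spec objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import ImageVolume, RoiMask

__all__ = [
    "PhantomSpec",
    "ReconSpec",
    "ReaderSpec",
    "CohortRecord",
    "generate_phantom",
    "simulate_reconstructions",
    "simulate_reader",
    "generate_cohort",
    "apply_exclusions",
    "sample_phantom_spec",
    "dice",
]

#: Primary sites observed in the emulated oncology cohort.
PRIMARY_SITES = (
    "lung", "colon", "breast", "renal", "rectal", "ampulla_of_Vater",
    "nasopharyngeal", "ovarian", "salivary_gland", "other",
)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tumor phantom.

    Defaults emulate the study conditions: 0.68 x 0.68 x 1.00 mm voxels and a
    lesion of ~22.6 mm diameter (the cohort mean) in -800 HU lung background.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.68, 0.68, 1.00)
    radii_mm: tuple[float, float, float] = (11.3, 11.3, 11.3)
    lobulation: float = 0.15          # fractional radial modulation amplitude
    core_hu: float = 55.0             # contrast-enhanced solid tumor plateau
    rim_hu: float = -150.0            # partial-volume rim toward lung
    necrosis_fraction: float = 0.10   # volume fraction of low-attenuation core
    background_hu: float = -800.0     # aerated lung parenchyma
    seed: int = 0
    texture_hu_sd: float = 12.0       # smooth intra-tumoral texture (HU)
    rim_width: float = 0.30           # rim thickness as fraction of radius
    lobulation_correlation_mm: float = 4.0
    texture_correlation_mm: float = 2.0
    boundary_pv_fraction: float = 0.002  # fraction of voxels with deep partial-volume values
    boundary_pv_shell: float = 0.85      # normalized radius where those voxels may occur

    def __post_init__(self) -> None:
        if not (0.0 <= self.necrosis_fraction < 1.0):
            raise ValueError(f"necrosis_fraction must be in [0, 1), got {self.necrosis_fraction}")
        if self.lobulation < 0:
            raise ValueError("lobulation amplitude must be >= 0")
        half_extent = [n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing)]
        margin = 2.0  # mm of clearance so the rim decays inside the grid
        for r, h in zip(self.radii_mm, half_extent):
            if r * (1.0 + self.lobulation) + margin > h:
                raise ValueError(
                    f"tumor radius {r} mm (with lobulation) exceeds grid half-extent {h} mm"
                )


@dataclass
class ReconSpec:
    """Noise model linking the FBP-like and iterative-like variants.

    One correlated Gaussian noise field is drawn and added at full amplitude
    (``noise_sd_fbp``) for FBP, and scaled by the reduction factors for S3
    and S5.  In the default study configuration 0 < r_s5 < r_s3 < 1, i.e.
    S5 suppresses noise more than S3.
    """

    noise_sd_fbp: float = 60.0            # HU, half-dose sharp-kernel chest CT
    noise_correlation_length: float = 0.5  # mm; B50f-like noise is high-frequency
    r_s3: float = 0.60
    r_s5: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.noise_sd_fbp > 0):
            raise ValueError(f"noise_sd_fbp must be positive, got {self.noise_sd_fbp}")
        if not (0.0 < self.r_s5 <= self.r_s3 <= 1.0):
            raise ValueError(
                f"reduction factors must satisfy 0 < r_s5 <= r_s3 <= 1, "
                f"got r_s3={self.r_s3}, r_s5={self.r_s5}"
            )


@dataclass
class ReaderSpec:
    """One reader's segmentation behavior across repeat sessions."""

    reader_id: str
    boundary_jitter_amplitude: float = 0.3  # mm, typical manual-contour wobble
    session_seeds: tuple[int, ...] = (0, 1)
    jitter_correlation_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.boundary_jitter_amplitude < 0:
            raise ValueError("boundary_jitter_amplitude must be >= 0")


@dataclass
class CohortRecord:
    """One screened patient with the exclusion flags used by the study."""

    patient_id: str
    has_measurable_lesion: bool = True
    is_ground_glass: bool = False
    primary_site: str = "lung"


def _smooth_field(
    shape: Sequence[int],
    spacing: Sequence[float],
    correlation_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with the given correlation length."""
    white = rng.standard_normal(tuple(shape))
    if correlation_mm <= 0:
        return white
    sigma = [correlation_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma)
    sd = smooth.std()
    if sd == 0:
        return np.zeros_like(smooth)
    return (smooth - smooth.mean()) / sd


def _grid_coordinates(shape, spacing):
    axes = [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, RoiMask]:
    """Build one noise-free tumor phantom and its ground-truth mask.

    The tumor support is a lobulated ellipsoid: the normalized ellipsoidal
    radius is modulated by a smooth random field scaled to ``lobulation``.
    Intensity is the core plateau inside, a linear ramp to ``rim_hu`` over
    the outer ``rim_width`` of the radius, a short decay to lung background
    outside, and an optional central necrotic region; a smooth low-amplitude
    texture field is superimposed.  A sparse fraction of outer-shell voxels
    (``boundary_pv_fraction``) takes deep partial-volume values toward lung
    attenuation, as real tumor-lung interface voxels do; these give the
    in-mask histogram its long left tail.  Deterministic given ``spec.seed``;
    the returned mask is the exact generative support.
    """
    rng = np.random.default_rng(spec.seed)
    x, y, z = _grid_coordinates(spec.grid_shape, spec.spacing)
    rx, ry, rz = spec.radii_mm
    f0 = np.sqrt((x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2)

    if spec.lobulation > 0:
        lob_field = _smooth_field(
            spec.grid_shape, spec.spacing, spec.lobulation_correlation_mm, rng
        )
        # bound the modulation so the lobulated radius stays within (1 +/- lobulation)
        modulation = 1.0 + spec.lobulation * np.clip(lob_field / 3.0, -1.0, 1.0)
    else:
        rng.standard_normal(tuple(spec.grid_shape))  # keep the stream aligned
        modulation = np.ones(spec.grid_shape)

    f = f0 / modulation
    mask = f <= 1.0
    if not mask.any():
        raise ValueError("phantom mask is empty; radii too small for the grid")

    core_start = 1.0 - spec.rim_width
    t_rim = np.clip((f - core_start) / max(spec.rim_width, 1e-9), 0.0, 1.0)
    inside = spec.core_hu + (spec.rim_hu - spec.core_hu) * t_rim
    edge_width = 0.2  # decay from rim to background, as fraction of radius
    t_out = np.clip((f - 1.0) / edge_width, 0.0, 1.0)
    data = np.where(
        mask, inside, spec.rim_hu + (spec.background_hu - spec.rim_hu) * t_out
    )

    if spec.necrosis_fraction > 0:
        necro = f <= spec.necrosis_fraction ** (1.0 / 3.0)
        data = np.where(necro, spec.core_hu - 50.0, data)

    if spec.texture_hu_sd > 0:
        texture = _smooth_field(
            spec.grid_shape, spec.spacing, spec.texture_correlation_mm, rng
        )
        data = data + spec.texture_hu_sd * texture

    if spec.boundary_pv_fraction > 0:
        shell = mask & (f >= spec.boundary_pv_shell)
        candidates = np.flatnonzero(shell)
        k = max(1, int(round(spec.boundary_pv_fraction * mask.sum())))
        if candidates.size:
            chosen = rng.choice(candidates, size=min(k, candidates.size), replace=False)
            mix = rng.uniform(0.75, 1.0, size=chosen.size)
            flat = data.reshape(-1)
            flat[chosen] = spec.rim_hu + (spec.background_hu - spec.rim_hu) * mix

    volume = ImageVolume(data=data.astype(np.float64), spacing=spec.spacing,
                         algorithm_label="clean")
    return volume, RoiMask(mask=mask, spacing=spec.spacing)


def simulate_reconstructions(
    clean: ImageVolume, spec: ReconSpec
) -> dict[str, ImageVolume]:
    """Emulate FBP/S3/S5 variants of one acquisition.

    Draws a single correlated noise field (seeded) and adds it at full
    amplitude for FBP, scaled by ``r_s3`` and ``r_s5`` for the iterative
    variants; the anatomy is identical across the three outputs.
    """
    rng = np.random.default_rng(spec.seed)
    fld = _smooth_field(clean.shape, clean.spacing, spec.noise_correlation_length, rng)
    out = {}
    for label, scale in (("FBP", 1.0), ("S3", spec.r_s3), ("S5", spec.r_s5)):
        out[label] = ImageVolume(
            data=clean.data + spec.noise_sd_fbp * scale * fld,
            spacing=clean.spacing,
            algorithm_label=label,
        )
    return out


def simulate_reader(truth: RoiMask, spec: ReaderSpec, session: int = 1) -> RoiMask:
    """Simulate one manual segmentation of the ground-truth lesion.

    The signed Euclidean boundary distance (mm, anisotropy-aware) is
    perturbed by a smooth random field scaled to the reader's jitter
    amplitude, then re-thresholded; the largest connected component is kept.
    Deterministic per (reader, session) via ``session_seeds``.  Amplitude 0
    reproduces the truth exactly.
    """
    if truth.voxel_count == 0:
        raise ValueError("ground-truth mask is empty")
    if session < 1 or session > len(spec.session_seeds):
        raise ValueError(
            f"session {session} has no seed; reader {spec.reader_id!r} defines "
            f"{len(spec.session_seeds)} sessions"
        )
    if spec.boundary_jitter_amplitude == 0:
        return RoiMask(mask=truth.mask.copy(), spacing=truth.spacing)
    rng = np.random.default_rng(spec.session_seeds[session - 1])
    d_in = ndimage.distance_transform_edt(truth.mask, sampling=truth.spacing)
    d_out = ndimage.distance_transform_edt(~truth.mask, sampling=truth.spacing)
    signed = d_in - d_out
    fld = _smooth_field(truth.shape, truth.spacing, spec.jitter_correlation_mm, rng)
    new_mask = (signed + spec.boundary_jitter_amplitude * fld) > 0
    labeled, n_comp = ndimage.label(new_mask)
    if n_comp == 0:
        raise ValueError("jitter amplitude emptied the mask")
    if n_comp > 1:
        sizes = ndimage.sum_labels(new_mask, labeled, index=range(1, n_comp + 1))
        new_mask = labeled == (int(np.argmax(sizes)) + 1)
    return RoiMask(mask=new_mask, spacing=truth.spacing)


def generate_cohort(
    n_patients: int = 47,
    n_without_lesion: int = 4,
    n_ground_glass: int = 1,
    seed: int = 0,
) -> list[CohortRecord]:
    """A screening cohort with the exclusion flags set on random patients.

    Defaults reproduce the study's screening numbers: 47 screened, 4 without
    a measurable lesion, 1 ground-glass nodule.
    """
    if n_without_lesion + n_ground_glass > n_patients:
        raise ValueError("more flagged patients than patients")
    rng = np.random.default_rng(seed)
    flagged = rng.choice(n_patients, size=n_without_lesion + n_ground_glass, replace=False)
    no_lesion = set(flagged[:n_without_lesion].tolist())
    ground_glass = set(flagged[n_without_lesion:].tolist())
    cohort = []
    for i in range(n_patients):
        cohort.append(
            CohortRecord(
                patient_id=f"P{i + 1:03d}",
                has_measurable_lesion=i not in no_lesion,
                is_ground_glass=i in ground_glass,
                primary_site=str(rng.choice(PRIMARY_SITES)),
            )
        )
    return cohort


def apply_exclusions(cohort: Sequence[CohortRecord]) -> list[CohortRecord]:
    """Drop patients without a measurable lesion or with a ground-glass nodule."""
    return [
        rec for rec in cohort
        if rec.has_measurable_lesion and not rec.is_ground_glass
    ]


def sample_phantom_spec(
    rng: np.random.Generator,
    grid_shape: tuple[int, int, int] = (96, 96, 64),
    spacing: tuple[float, float, float] = (0.68, 0.68, 1.00),
    size_mean_mm: float = 22.6,
    size_sd_mm: float = 8.5,
    size_range_mm: tuple[float, float] = (10.0, 41.7),
    **overrides,
) -> PhantomSpec:
    """Draw one lesion's phantom spec from the cohort size distribution.

    Lesion diameter is a truncated normal (mean 22.6 mm, SD 8.5 mm, range
    10.0-41.7 mm, the cohort's reported distribution); mild per-axis
    anisotropy is applied with the geometric mean preserved.
    """
    lo, hi = size_range_mm
    while True:
        d = rng.normal(size_mean_mm, size_sd_mm)
        if lo <= d <= hi:
            break
    anis = rng.uniform(0.85, 1.18, size=3)
    anis /= anis.prod() ** (1.0 / 3.0)
    radii = tuple(float(d / 2.0 * a) for a in anis)
    seed = int(rng.integers(0, 2**31 - 1))
    return PhantomSpec(
        grid_shape=grid_shape, spacing=spacing, radii_mm=radii, seed=seed, **overrides
    )


def dice(a: RoiMask, b: RoiMask) -> float:
    """Dice overlap coefficient between two masks on the same grid."""
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    inter = np.logical_and(a.mask, b.mask).sum()
    denom = a.voxel_count + b.voxel_count
    if denom == 0:
        return math.nan
    return 2.0 * float(inter) / float(denom)
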