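"""Domain types, image/mask I/O, and ROI propagation.

The unit of measurement is an :class:`ImageVolume`: a 3D scalar grid in
Hounsfield units with anisotropic voxel spacing and a reconstruction label
(``FBP``, ``S3``, ``S5`` or free text).  A :class:`RoiMask` is a binary tumor
segmentation on the same grid.  The central study operation is
:func:`propagate_roi`, which applies one segmentation unchanged to every
reconstruction variant of the same acquisition — this is what makes shape
features bitwise identical across variants and isolates the reconstruction
effect in texture features.

Arrays are indexed ``(x, y, z)`` with spacing ``(dx, dy, dz)`` in mm; both
supported file formats (NIfTI-1 via nibabel, NRRD via SimpleITK) are converted
to this convention on read.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "FEATURE_NAMES",
    "SHAPE_FEATURE_NAMES",
    "ImageVolume",
    "RoiMask",
    "FeatureVector",
    "MeasurementRecord",
    "DoseRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "propagate_roi",
    "compute_effective_dose",
]

#: Serialization order of the 15 radiomic features.
FEATURE_NAMES = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "entropy",
    "homogeneity",
    "volume",
    "effective_diameter",
    "surface_area",
    "sphericity",
    "discrete_compactness",
    "glcm_moments",
    "glcm_idm",
    "glcm_contrast",
    "glcm_entropy",
)

#: Features that depend only on the mask, never on intensities.
SHAPE_FEATURE_NAMES = (
    "volume",
    "effective_diameter",
    "surface_area",
    "sphericity",
    "discrete_compactness",
)

#: ICRP publication 103 chest conversion factor, mSv per mGy·cm.
DEFAULT_DOSE_CONVERSION = 0.0145


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not (s > 0) for s in spacing):
        raise ValueError(f"spacing components must be strictly positive, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar image in HU on an anisotropic voxel grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    algorithm_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"each axis must have length >= 1, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """A binary segmentation aligned to an :class:`ImageVolume` grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.mask.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def check_compatible(self, volume: ImageVolume, name: str = "volume") -> None:
        """Raise if ``volume`` does not share this mask's grid."""
        if volume.shape != self.shape:
            raise ValueError(
                f"{name}: grid mismatch, mask shape {self.shape} vs volume shape {volume.shape}"
            )
        if not np.allclose(volume.spacing, self.spacing):
            raise ValueError(
                f"{name}: spacing mismatch, mask {self.spacing} vs volume {volume.spacing}"
            )


@dataclass
class FeatureVector:
    """The 15 radiomic feature values for one measurement.

    First-order intensity: mean (HU), sd (HU), skewness, excess kurtosis,
    histogram entropy (bits), histogram homogeneity (uniformity, in (0, 1]).
    Size/shape: volume (mm³), effective diameter (mm), surface area (mm²),
    sphericity, discrete compactness.  GLCM: angular second moment, inverse
    difference moment, contrast (squared gray-level units), entropy (nats).
    Undefined values (e.g. skewness of a constant ROI) are NaN sentinels.
    """

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    entropy: float
    homogeneity: float
    volume: float
    effective_diameter: float
    surface_area: float
    sphericity: float
    discrete_compactness: float
    glcm_moments: float
    glcm_idm: float
    glcm_contrast: float
    glcm_entropy: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "FeatureVector":
        return cls(**{name: float(values[name]) for name in FEATURE_NAMES})


@dataclass
class MeasurementRecord:
    """One feature extraction: (lesion, reader, session, algorithm) -> features."""

    lesion_id: str
    reader_id: str
    session: int
    algorithm_label: str
    features: FeatureVector

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.lesion_id, self.reader_id, self.session, self.algorithm_label)


@dataclass
class DoseRecord:
    """CT dose indices for one scan; effective dose derives from DLP."""

    ctdi_vol: float
    dlp: float
    conversion_factor: float = DEFAULT_DOSE_CONVERSION
    effective_dose: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = compute_effective_dose(self.dlp, self.conversion_factor)
        if self.effective_dose is None:
            self.effective_dose = expected
        elif not math.isclose(self.effective_dose, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"effective_dose {self.effective_dose} inconsistent with "
                f"dlp x conversion_factor = {expected}"
            )


def compute_effective_dose(dlp: float, conversion_factor: float = DEFAULT_DOSE_CONVERSION) -> float:
    """Effective dose in mSv from dose-length product (mGy·cm).

    Uses the anatomic conversion factor (default 0.0145 mSv/(mGy·cm), the
    ICRP 103 chest value).
    """
    if dlp < 0:
        raise ValueError(f"dlp must be non-negative, got {dlp}")
    if conversion_factor <= 0:
        raise ValueError(f"conversion_factor must be positive, got {conversion_factor}")
    return float(dlp) * float(conversion_factor)


# ---------------------------------------------------------------------------
# File I/O.  Internal convention: arrays indexed (x, y, z), spacing (dx, dy, dz).
# nibabel already yields (i, j, k) == (x, y, z); SimpleITK arrays arrive
# (z, y, x) and are transposed.
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_NRRD_SUFFIXES = (".nrrd", ".nhdr")


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("nifti", "nrrd"):
            raise ValueError(f"unknown format {fmt!r}; expected 'nifti' or 'nrrd'")
        return fmt
    lower = str(path).lower()
    if any(lower.endswith(s) for s in _NIFTI_SUFFIXES):
        return "nifti"
    if any(lower.endswith(s) for s in _NRRD_SUFFIXES):
        return "nrrd"
    raise ValueError(f"cannot infer image format from path {path!r}")


def read_volume(path: str, format: str | None = None, algorithm_label: str = "") -> ImageVolume:
    """Read a 3D scalar image (NIfTI or NRRD) into the internal convention.

    Intensities are passed through unchanged; spacing comes from the header.
    Raises on missing files, non-3D images, and missing/zero spacing (the
    error names the offending header field).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    fmt = _detect_format(path, format)
    if fmt == "nifti":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {data.ndim} in {path}")
        # read the on-disk pixdim without nibabel's auto-repair of zero values
        with nib.openers.ImageOpener(path, "rb") as fobj:
            raw_hdr = nib.Nifti1Header.from_fileobj(fobj, check=False)
        raw_pixdim = tuple(float(z) for z in raw_hdr["pixdim"][1:4])
        if any(not (z > 0) for z in raw_pixdim):
            raise ValueError(
                f"NIfTI header field 'pixdim' has missing/zero spacing {raw_pixdim} in {path}"
            )
        zooms = img.header.get_zooms()[:3]
        return ImageVolume(data=data, spacing=tuple(float(z) for z in zooms),
                           algorithm_label=algorithm_label)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3 dimensions, got {img.GetDimension()} in {path}")
    spacing = img.GetSpacing()  # (x, y, z)
    if any(not (s > 0) for s in spacing):
        raise ValueError(
            f"NRRD header field 'spacings'/'space directions' has missing/zero "
            f"spacing {tuple(spacing)} in {path}"
        )
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    return ImageVolume(data=data, spacing=tuple(float(s) for s in spacing),
                       algorithm_label=algorithm_label)


def write_volume(volume: ImageVolume, path: str, format: str | None = None) -> None:
    """Write an :class:`ImageVolume` as NIfTI or NRRD (inferred from suffix)."""
    fmt = _detect_format(path, format)
    if fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        img = nib.Nifti1Image(volume.data, affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, path)
        return
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing))
    sitk.WriteImage(img, str(path))


def read_mask(path: str, format: str | None = None) -> RoiMask:
    """Read a binary ROI mask stored as integer 0/1 voxels."""
    vol = read_volume(path, format=format)
    return RoiMask(mask=vol.data > 0, spacing=vol.spacing)


def write_mask(mask: RoiMask, path: str, format: str | None = None) -> None:
    write_volume(
        ImageVolume(data=mask.mask.astype(np.uint8), spacing=mask.spacing), path, format=format
    )


def propagate_roi(
    roi: RoiMask, volumes: Iterable[ImageVolume]
) -> dict[str, tuple[ImageVolume, RoiMask]]:
    """Copy-and-paste one segmentation onto every reconstruction variant.

    Every returned pair carries a bit-identical copy of the input mask; no
    per-volume re-segmentation occurs, so mask cardinality (and hence every
    shape feature) is identical across variants.  Any grid mismatch raises,
    naming the offending volume.
    """
    out: dict[str, tuple[ImageVolume, RoiMask]] = {}
    for i, vol in enumerate(volumes):
        label = vol.algorithm_label or f"volume_{i}"
        roi.check_compatible(vol, name=f"volume {label!r}")
        out[label] = (vol, RoiMask(mask=roi.mask.copy(), spacing=roi.spacing))
    return out
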