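"""3D gray-level co-occurrence matrix and its four texture features.

In-mask intensities are linearly quantized to G levels, then gray-level pairs
are accumulated for every in-mask voxel whose displaced partner is also
in-mask, over the 13 unique 3D directions (or the 3 axial ones) at a fixed
voxel distance.  Both (i, j) and (j, i) are counted, so the normalized matrix
is symmetric; normalization is by the realized pair count (mask-aware), the
only well-defined choice for irregular ROIs.

Features on the normalized p(i, j):

    contrast = sum (i - j)^2 p(i, j)
    idm      = sum p(i, j) / (1 + (i - j)^2)
    entropy  = -sum p ln p            (nats, nonzero cells)
    moments  = sum p(i, j)^2          (angular second moment, default)

Defaults G = 256, distance 1, all 13 directions pooled into one symmetric
matrix; all configurable.  GLCM entropy is in nats while first-order entropy
is in bits — the two conventions are deliberate, independent, and recorded in
study output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageVolume, RoiMask

__all__ = [
    "QuantizedRoi",
    "GlcmMatrix",
    "GlcmFeatures",
    "OFFSETS_ALL13",
    "OFFSETS_AXIAL3",
    "quantize",
    "build_glcm",
    "glcm_features",
    "glcm_features_from_roi",
]

DEFAULT_LEVELS = 256

#: The 13 unique 3D displacement directions (one per antipodal pair).
OFFSETS_ALL13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0),
    (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: Axis-aligned directions only.
OFFSETS_AXIAL3: tuple[tuple[int, int, int], ...] = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

_DIRECTION_SETS = {"all13": OFFSETS_ALL13, "axial3": OFFSETS_AXIAL3}


@dataclass
class QuantizedRoi:
    """Gray levels in [0, G-1] defined on mask voxels."""

    levels: np.ndarray
    mask: np.ndarray
    G: int
    calibration: tuple[float, float]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.G < 2:
            raise ValueError(f"need G >= 2 gray levels, got {self.G}")
        in_mask = self.levels[self.mask]
        if in_mask.size and (in_mask.min() < 0 or in_mask.max() > self.G - 1):
            raise ValueError("in-mask levels fall outside [0, G-1]")


@dataclass
class GlcmMatrix:
    """Normalized symmetric G x G co-occurrence probability table."""

    p: np.ndarray
    offsets_used: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)
    pair_count: int = 0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError(f"p must be square, got shape {self.p.shape}")
        if np.any(self.p < 0):
            raise ValueError("p must be nonnegative")

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.p.sum()) - 1.0) <= 1e-9


@dataclass
class GlcmFeatures:
    moments: float
    idm: float
    contrast: float
    entropy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "glcm_moments": self.moments,
            "glcm_idm": self.idm,
            "glcm_contrast": self.contrast,
            "glcm_entropy": self.entropy,
        }


def quantize(volume: ImageVolume, roi: RoiMask, G: int = DEFAULT_LEVELS) -> QuantizedRoi:
    """Linearly map in-mask intensities onto integer levels [0, G-1].

    level = floor((x - min) / (max - min) * G), clamped to G-1, with min/max
    taken over the in-mask voxels.  A constant ROI maps entirely to level 0.
    """
    roi.check_compatible(volume)
    if roi.voxel_count == 0:
        raise ValueError("empty mask: nothing to quantize")
    if G < 2:
        raise ValueError(f"need G >= 2 gray levels, got {G}")
    data = np.asarray(volume.data, dtype=float)
    in_mask = data[roi.mask]
    vmin, vmax = float(in_mask.min()), float(in_mask.max())
    levels = np.zeros(data.shape, dtype=np.int32)
    if vmax > vmin:
        # clip in float first: out-of-mask voxels may hold arbitrary values
        scaled = np.floor((data - vmin) / (vmax - vmin) * G)
        levels = np.clip(scaled, 0, G - 1).astype(np.int32)
    return QuantizedRoi(levels=levels, mask=roi.mask, G=G, calibration=(vmin, vmax))


def build_glcm(q: QuantizedRoi, distance: int = 1, directions: str = "all13") -> GlcmMatrix:
    """Accumulate the symmetric co-occurrence matrix over the mask.

    For each direction offset (scaled by ``distance``) and each in-mask voxel
    whose offset partner is also in-mask, both (i, j) and (j, i) are counted;
    voxels outside the mask never contribute.  Raises if no valid pair exists
    (e.g. a single-voxel mask).
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    try:
        offsets = _DIRECTION_SETS[directions]
    except KeyError:
        raise ValueError(f"unknown direction set {directions!r}; expected 'all13' or 'axial3'")
    G = q.G
    counts = np.zeros(G * G, dtype=np.int64)
    shape = q.levels.shape
    for off in offsets:
        d = tuple(o * distance for o in off)
        src = tuple(
            slice(max(0, -dk), min(nk, nk - dk)) for dk, nk in zip(d, shape)
        )
        dst = tuple(
            slice(max(0, dk), min(nk, nk + dk)) for dk, nk in zip(d, shape)
        )
        valid = q.mask[src] & q.mask[dst]
        if not valid.any():
            continue
        i = q.levels[src][valid].astype(np.int64)
        j = q.levels[dst][valid].astype(np.int64)
        counts += np.bincount(i * G + j, minlength=G * G)
        counts += np.bincount(j * G + i, minlength=G * G)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no co-occurring pairs within the mask")
    p = counts.reshape(G, G) / total
    return GlcmMatrix(p=p, offsets_used=offsets, pair_count=total)


def glcm_features(m: GlcmMatrix, moments_definition: str = "asm") -> GlcmFeatures:
    """Contrast, IDM, entropy (nats) and moments from a normalized matrix.

    ``moments_definition`` selects what the loosely-named "moments" feature
    computes: ``asm`` (angular second moment, default) or ``diff_moment2``
    (second moment of |i - j| on the unit-scaled level axis).
    """
    if not m.is_normalized:
        raise ValueError("GLCM must be normalized (probabilities summing to 1)")
    G = m.p.shape[0]
    i, j = np.meshgrid(np.arange(G), np.arange(G), indexing="ij")
    diff2 = (i - j) ** 2
    contrast = float((diff2 * m.p).sum())
    idm = float((m.p / (1.0 + diff2)).sum())
    nz = m.p[m.p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    if moments_definition == "asm":
        moments = float((m.p ** 2).sum())
    elif moments_definition == "diff_moment2":
        moments = float((diff2 / (G - 1) ** 2 * m.p).sum())
    else:
        raise ValueError(f"unknown moments definition {moments_definition!r}")
    return GlcmFeatures(moments=moments, idm=idm, contrast=contrast, entropy=entropy)


def glcm_features_from_roi(
    volume: ImageVolume,
    roi: RoiMask,
    G: int = DEFAULT_LEVELS,
    distance: int = 1,
    directions: str = "all13",
    moments_definition: str = "asm",
) -> GlcmFeatures:
    """Quantize, build the pooled matrix, and compute the four features."""
    q = quantize(volume, roi, G=G)
    m = build_glcm(q, distance=distance, directions=directions)
    return glcm_features(m, moments_definition=moments_definition)
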