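"""Size/shape features from the binary mask.

Five features: volume, effective diameter, surface area, sphericity, and
discrete compactness.  All depend only on the mask, never on intensities, so
a segmentation propagated across reconstruction variants yields exactly equal
shape features on every variant.

Surface area defaults to the triangle area of the 0.5-level isosurface of the
(zero-padded) binary mask, scaled by voxel spacing; the exposed-voxel-face
count is kept as a cross-check.  The two bracket the true surface of smooth
shapes: staircase faces overestimate, the mesh converges from near above/below.

Discrete compactness follows the contact-area normalization of Bribiesca:
with n voxels and A_c face-adjacent voxel pairs,

    DC = (A_c - (n - 1)) / (3 (n - n^(2/3)) - (n - 1))

0 for a chain (minimal contact among connected sets), 1 for a perfect cube.
It is defined on voxel topology and ignores spacing anisotropy.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import RoiMask

__all__ = [
    "mask_volume",
    "effective_diameter",
    "surface_area",
    "sphericity",
    "discrete_compactness",
    "extract_surface_mesh",
    "export_mesh_ply",
    "shape_features",
]


def _require_nonempty(roi: RoiMask) -> None:
    if roi.voxel_count == 0:
        raise ValueError("empty mask: shape features undefined")


def mask_volume(roi: RoiMask) -> float:
    """Mask volume in mm³: set-voxel count times voxel volume."""
    _require_nonempty(roi)
    return roi.voxel_count * roi.voxel_volume


def effective_diameter(volume: float) -> float:
    """Diameter (mm) of the sphere with the given volume (mm³)."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


def extract_surface_mesh(
    roi: RoiMask, smoothing_voxels: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Vertices (mm) and triangle indices of the mask's 0.5-level isosurface.

    The mask is zero-padded first so boundary-touching masks still produce a
    closed, watertight triangulation, and anti-aliased with a small Gaussian
    (``smoothing_voxels`` in index units) before extraction — the raw binary
    staircase otherwise overestimates the area of smooth shapes by ~8%.  For
    masks so small that smoothing erases the 0.5 level set, the raw binary
    mask is used instead.
    """
    _require_nonempty(roi)
    pad = max(1, int(math.ceil(3 * smoothing_voxels)))
    padded = np.pad(roi.mask, pad).astype(np.float32)
    field = padded
    if smoothing_voxels > 0:
        smoothed = ndimage.gaussian_filter(padded, sigma=smoothing_voxels)
        if smoothed.max() > 0.5:
            field = smoothed
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=roi.spacing)
    verts = verts - pad * np.asarray(roi.spacing)  # undo the pad offset
    return verts, faces


def surface_area(roi: RoiMask, method: str = "mesh") -> float:
    """Surface area in mm².

    ``mesh``: total triangle area of the spacing-scaled isosurface.
    ``voxel_faces``: exposed voxel faces times per-face area (staircase;
    systematically larger for smooth shapes).
    """
    _require_nonempty(roi)
    if method == "mesh":
        verts, faces = extract_surface_mesh(roi)
        return float(measure.mesh_surface_area(verts, faces))
    if method == "voxel_faces":
        m = roi.mask
        dx, dy, dz = roi.spacing
        face_area = (dy * dz, dx * dz, dx * dy)  # faces normal to x, y, z
        total = 0.0
        for axis, area in enumerate(face_area):
            diff = np.abs(np.diff(m.astype(np.int8), axis=axis)).sum()
            first = np.take(m, 0, axis=axis).sum()
            last = np.take(m, -1, axis=axis).sum()
            total += (int(diff) + int(first) + int(last)) * area
        return float(total)
    raise ValueError(f"unknown surface area method {method!r}")


def sphericity(volume: float, sa: float) -> float:
    """pi^(1/3) (6 V)^(2/3) / SA — 1 for a perfect sphere."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if sa <= 0:
        raise ValueError(f"surface area must be positive, got {sa}")
    return math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / sa


def _face_contacts(mask: np.ndarray) -> int:
    """Number of 6-connected (face-adjacent) voxel pairs in the mask."""
    total = 0
    for axis in range(3):
        a = np.take(mask, range(mask.shape[axis] - 1), axis=axis)
        b = np.take(mask, range(1, mask.shape[axis]), axis=axis)
        total += int(np.logical_and(a, b).sum())
    return total


def discrete_compactness(roi: RoiMask) -> float:
    """Bribiesca discrete compactness on 6-connected voxel topology.

    Returns NaN (undefined sentinel) for masks with fewer than 2 voxels.
    Disconnected masks are allowed but emit a warning.
    """
    n = roi.voxel_count
    if n < 2:
        warnings.warn("discrete compactness undefined for masks with < 2 voxels")
        return math.nan
    _, n_components = ndimage.label(roi.mask)
    if n_components > 1:
        warnings.warn(f"mask has {n_components} disconnected components")
    a_c = _face_contacts(roi.mask)
    a_min = n - 1
    a_max = 3.0 * (n - n ** (2.0 / 3.0))
    return (a_c - a_min) / (a_max - a_min)


def export_mesh_ply(roi: RoiMask, path: str) -> None:
    """Write the mask isosurface as an ASCII PLY file (debugging aid)."""
    verts, faces = extract_surface_mesh(roi)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in verts:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def shape_features(roi: RoiMask, sa_method: str = "mesh") -> dict[str, float]:
    """All five shape features as a name -> value mapping."""
    vol = mask_volume(roi)
    sa = surface_area(roi, method=sa_method)
    return {
        "volume": vol,
        "effective_diameter": effective_diameter(vol),
        "surface_area": sa,
        "sphericity": sphericity(vol, sa),
        "discrete_compactness": discrete_compactness(roi),
    }
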