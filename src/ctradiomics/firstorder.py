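"""First-order intensity features over the masked voxel set.

Six features: mean, sample SD, skewness (g1), excess kurtosis (g2), histogram
entropy, and histogram homogeneity (uniformity).  Skewness/kurtosis use the
biased 1/n central-moment estimators; the excess convention makes a Gaussian
score 0 and admits negative values.

Entropy and homogeneity are computed on an equal-width histogram over the
ROI's own [min, max]:

    entropy     = -sum_i p_i log2 p_i       (bits, nonzero bins)
    homogeneity = sum_i p_i**2              (uniformity, in (0, 1])

Defaults: 256 bins, log base 2.  Both are configurable because they rescale
results; the configuration is recorded in study output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ImageVolume, RoiMask

__all__ = [
    "IntensityHistogram",
    "FirstOrderFeatures",
    "masked_intensities",
    "intensity_histogram",
    "firstorder_features",
]

DEFAULT_BINS = 256


@dataclass
class IntensityHistogram:
    """Equal-width intensity histogram: B+1 ascending edges, B probabilities."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.size < 1:
            raise ValueError("histogram must have at least one bin")
        if self.bin_edges.size != self.probabilities.size + 1:
            raise ValueError("need B+1 edges for B probabilities")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


@dataclass
class FirstOrderFeatures:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    entropy: float
    homogeneity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "entropy": self.entropy,
            "homogeneity": self.homogeneity,
        }


def masked_intensities(volume: ImageVolume, roi: RoiMask) -> np.ndarray:
    """Intensities of exactly the set voxels, in C raster order."""
    roi.check_compatible(volume)
    if roi.voxel_count == 0:
        raise ValueError("empty mask: no voxels to extract")
    return np.asarray(volume.data[roi.mask], dtype=float)


def intensity_histogram(values: np.ndarray, bins: int = DEFAULT_BINS) -> IntensityHistogram:
    """Equal-width histogram over [min, max] of the values.

    A constant input collapses to a single bin with probability 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty value set")
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return IntensityHistogram(
            bin_edges=np.array([vmin, vmin + 1.0]), probabilities=np.array([1.0])
        )
    counts, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    return IntensityHistogram(bin_edges=edges, probabilities=counts / values.size)


def firstorder_features(
    values: np.ndarray, bins: int = DEFAULT_BINS, log_base: float = 2.0
) -> FirstOrderFeatures:
    """Compute the six first-order features from a list of HU values.

    Requires n >= 2.  For constant input sd = 0, entropy = 0, homogeneity = 1,
    and skewness/kurtosis are NaN sentinels (undefined, not zero).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        skewness = math.nan
        kurtosis = math.nan
    else:
        # biased 1/n central-moment estimators: g1, g2 (excess)
        skewness = float(sps.skew(values, bias=True))
        kurtosis = float(sps.kurtosis(values, fisher=True, bias=True))
    hist = intensity_histogram(values, bins=bins)
    p = hist.probabilities[hist.probabilities > 0]
    entropy = float(-(p * (np.log(p) / math.log(log_base))).sum())
    homogeneity = float((p ** 2).sum())
    return FirstOrderFeatures(
        mean=mean,
        sd=sd,
        skewness=skewness,
        kurtosis=kurtosis,
        entropy=entropy,
        homogeneity=homogeneity,
    )
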