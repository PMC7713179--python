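"""Threshold-based artifact segmentation.

The algorithm quantifies metal artifacts without any physics model: a
material's "normal" CT-number range is its reference-region mean ± k·SD
(k = 3 by default, covering 99.7% of a Gaussian), and every voxel outside
that closed interval counts as artifact.  Applied inside a volume of
interest around the prosthesis this yields per-material artifact volumes.

Steps implemented here:
1. reference statistics over an artifact-free region (``region_stats``),
2. threshold derivation (``compute_thresholds``),
3. out-of-range classification (``classify_out_of_range``),
4. margin-safe masks via metric erosion (``erode_mask_mm``),
5. VOI propagation between co-registered series (``propagate_voi``) and the
   intersection with the out-of-range set (``segment_artifacts``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import RegionMask, VoxelVolume

__all__ = [
    "MaterialStats", "ThresholdPair",
    "region_stats", "compute_thresholds", "classify_out_of_range",
    "erode_mask_mm", "propagate_voi", "segment_artifacts",
]


@dataclass(frozen=True)
class MaterialStats:
    """Mean/SD/voxel-count of CT numbers in one region of one series."""

    material: str
    mean_hu: float
    sd_hu: float
    n_voxels: int
    source_series: str | None = None

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("statistics need at least 2 voxels")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper HU bounds of normal tissue for one material.

    Values inside the closed interval [lower, upper] are normal; values
    strictly beyond either bound are artifacts.
    """

    material: str
    lower_hu: float
    upper_hu: float
    k_sd: float = 3.0
    tube_potential_kvp: int | None = None

    def __post_init__(self) -> None:
        if self.lower_hu > self.upper_hu:
            raise ValueError("lower_hu must not exceed upper_hu")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")


def region_stats(
    vol: VoxelVolume,
    mask: RegionMask,
    material: str = "",
    source_series: str | None = None,
) -> MaterialStats:
    """Mean and sample SD (n−1 denominator) of the image over a binary region."""
    vol.grid.require_same(mask.grid, "volume and mask")
    values = vol.data[mask.data]
    if values.size == 0:
        raise ValueError("mask is empty")
    if values.size < 2:
        raise ValueError("mask must select at least 2 voxels")
    return MaterialStats(
        material=material,
        mean_hu=float(np.mean(values, dtype=np.float64)),
        sd_hu=float(np.std(values.astype(np.float64), ddof=1)),
        n_voxels=int(values.size),
        source_series=source_series,
    )


def compute_thresholds(
    stats: MaterialStats,
    k_sd: float = 3.0,
    tube_potential_kvp: int | None = None,
) -> ThresholdPair:
    """mean ± k·SD bounds; k = 3 encompasses 99.7% of normal Gaussian tissue."""
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    return ThresholdPair(
        material=stats.material,
        lower_hu=stats.mean_hu - k_sd * stats.sd_hu,
        upper_hu=stats.mean_hu + k_sd * stats.sd_hu,
        k_sd=k_sd,
        tube_potential_kvp=tube_potential_kvp,
    )


def classify_out_of_range(vol: VoxelVolume, thr: ThresholdPair) -> RegionMask:
    """Voxels strictly below the lower or strictly above the upper bound.

    Values exactly equal to a bound count as normal (closed interval).
    """
    data = vol.data
    return RegionMask((data < thr.lower_hu) | (data > thr.upper_hu), vol.grid)


def erode_mask_mm(mask: RegionMask, margin_mm: float) -> RegionMask:
    """Metric erosion: keep voxels farther than ``margin_mm`` from the complement.

    Distances are Euclidean in physical mm with anisotropic voxel spacing, so
    a 2 mm margin means 2 mm regardless of slice thickness.  May return an
    empty mask.  Margin 0 is the identity.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if margin_mm == 0 or not mask.data.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask.data, sampling=mask.grid.spacing_mm)
    return RegionMask(dist > margin_mm, mask.grid)


def propagate_voi(voi: RegionMask, target: VoxelVolume) -> RegionMask:
    """Bind a VOI drawn on one series to another co-registered series.

    There is no resampling: the target grid must match exactly (shape and
    spacing), mirroring acquisition of every series in the same position.
    """
    voi.grid.require_same(target.grid, "VOI and target series")
    return RegionMask(voi.data.copy(), target.grid)


def segment_artifacts(vol: VoxelVolume, thr: ThresholdPair, voi: RegionMask) -> RegionMask:
    """Artifact mask: out-of-range voxels intersected with the VOI."""
    vol.grid.require_same(voi.grid, "volume and VOI")
    return classify_out_of_range(vol, thr).intersect(voi)
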