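"""Artifact percentages, misclassification correction, noise and CNR.

The raw artifact percentage is |artifact ∩ VOI| / |VOI| · 100.  Because the
±3SD rule misclassifies ~0.27% of perfectly normal Gaussian voxels (2·Φ(−3)),
a per-series, per-material correction factor — the out-of-range percentage
measured on that series' own artifact-free reference region under the applied
thresholds — is subtracted from the raw percentage (floored at zero).

Noise is the SD of CT numbers in the water bath scanned *without* the
phantom.  CNR compares tissue to the water bath with the phantom present:
|Δmean| over the quadratic mean of the two SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .grids import RegionMask, VoxelVolume
from .segmentation import MaterialStats, ThresholdPair, classify_out_of_range

__all__ = [
    "ArtifactResult", "NoiseResult", "CnrResult",
    "artifact_fraction", "correction_factor", "corrected_fraction",
    "noise", "cnr", "distance_profile", "profile_trend",
    "expected_misclassified_percent", "expected_inlier_percent",
]


@dataclass(frozen=True)
class ArtifactResult:
    series: str
    material: str
    voi_voxels: int
    artifact_voxels: int
    raw_percent: float
    correction_percent: float
    corrected_percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.raw_percent <= 100:
            raise ValueError("raw_percent out of [0, 100]")
        if self.artifact_voxels > self.voi_voxels:
            raise ValueError("artifact volume cannot exceed VOI volume")
        expected = max(self.raw_percent - self.correction_percent, 0.0)
        if abs(self.corrected_percent - expected) > 1e-9:
            raise ValueError("corrected_percent must equal max(raw - correction, 0)")


@dataclass(frozen=True)
class NoiseResult:
    series: str
    noise_hu: float

    def __post_init__(self) -> None:
        if self.noise_hu < 0:
            raise ValueError("noise_hu must be >= 0")


@dataclass(frozen=True)
class CnrResult:
    series: str
    material: str
    cnr: float

    def __post_init__(self) -> None:
        if self.cnr < 0:
            raise ValueError("cnr must be >= 0")


def artifact_fraction(artifact: RegionMask, voi: RegionMask) -> float:
    """Artifact volume as a percentage of the VOI volume."""
    artifact.grid.require_same(voi.grid, "artifact mask and VOI")
    n_voi = voi.n_voxels
    if n_voi == 0:
        raise ValueError("VOI is empty")
    n_art = int((artifact.data & voi.data).sum())
    return 100.0 * n_art / n_voi


def correction_factor(vol: VoxelVolume, reference: RegionMask, thr: ThresholdPair) -> float:
    """Percentage of artifact-free reference voxels misclassified as artifacts.

    Equivalent to ``artifact_fraction`` with the reference region as the VOI;
    the reference is assumed artifact-free, so anything out of range is a
    false positive of the threshold rule.
    """
    return artifact_fraction(classify_out_of_range(vol, thr), reference)


def corrected_fraction(raw_percent: float, correction_percent: float) -> float:
    """Raw minus correction, floored at zero (negative artifact volume is
    meaningless)."""
    for v in (raw_percent, correction_percent):
        if not 0 <= v <= 100:
            raise ValueError("percentages must be in [0, 100]")
    return max(raw_percent - correction_percent, 0.0)


def noise(water_only_vol: VoxelVolume, water_mask: RegionMask,
          series: str = "") -> NoiseResult:
    """Image noise: sample SD of CT numbers in the phantom-free water bath."""
    water_only_vol.grid.require_same(water_mask.grid, "water volume and mask")
    values = water_only_vol.data[water_mask.data]
    if values.size < 2:
        raise ValueError("water mask must select at least 2 voxels")
    return NoiseResult(series, float(np.std(values.astype(np.float64), ddof=1)))


def cnr(tissue: MaterialStats, water_with_phantom: MaterialStats,
        method: str = "quadratic_mean", series: str = "") -> CnrResult:
    """Contrast-to-noise ratio of a tissue against the with-phantom water bath.

    ``quadratic_mean`` (default): |Δmean| / sqrt((SD_t² + SD_w²)/2) — the form
    that reproduces the published per-protocol CNR values.  ``water_sd``:
    |Δmean| / SD_w, the naive normalisation by water noise alone.
    """
    contrast = abs(tissue.mean_hu - water_with_phantom.mean_hu)
    if method == "quadratic_mean":
        denom = float(np.sqrt((tissue.sd_hu**2 + water_with_phantom.sd_hu**2) / 2.0))
    elif method == "water_sd":
        denom = water_with_phantom.sd_hu
    else:
        raise ValueError(f"unknown CNR method {method!r}")
    if denom == 0:
        if contrast == 0:
            return CnrResult(series, tissue.material, 0.0)
        raise ZeroDivisionError("zero pooled SD with non-zero contrast")
    return CnrResult(series, tissue.material, contrast / denom)


def distance_profile(
    artifact: RegionMask,
    voi: RegionMask,
    reference_z: int,
) -> list[tuple[float, float]]:
    """Per-slice artifact percentage vs distance from a reference slice.

    Returns ``(distance_mm, percent)`` pairs, one per VOI-covered slice,
    keyed by |z − reference_z| in mm and sorted by distance; slices where the
    VOI is empty are omitted.  Requires the VOI to span at least two slices.
    """
    artifact.grid.require_same(voi.grid, "artifact mask and VOI")
    dz = voi.grid.spacing_mm[0]
    voi_per_slice = voi.data.reshape(voi.grid.shape[0], -1).sum(axis=1)
    covered = np.nonzero(voi_per_slice)[0]
    if covered.size == 0:
        raise ValueError("VOI is empty on all slices")
    if covered.size < 2:
        raise ValueError("VOI must span at least 2 slices for a profile")
    art = (artifact.data & voi.data).reshape(voi.grid.shape[0], -1).sum(axis=1)
    profile = [
        (abs(int(iz) - int(reference_z)) * dz,
         100.0 * art[iz] / voi_per_slice[iz])
        for iz in covered
    ]
    return sorted(profile, key=lambda t: (t[0], t[1]))


def profile_trend(profile: list[tuple[float, float]]) -> float:
    """Spearman rank correlation of artifact percentage vs distance.

    Negative values indicate artifacts fading with distance from the
    prosthesis."""
    d, p = zip(*profile)
    if len(set(p)) == 1:  # flat profile: no trend
        return 0.0
    rho = sstats.spearmanr(d, p).statistic
    return float(rho)


def expected_misclassified_percent(k_sd: float = 3.0) -> float:
    """Analytic false-artifact rate of the ±k·SD rule on Gaussian data: 2·Φ(−k)·100."""
    return float(2.0 * sstats.norm.cdf(-k_sd) * 100.0)


def expected_inlier_percent(k_sd: float = 3.0) -> float:
    """Gaussian mass inside ±k·SD, in percent (99.7 for k = 3)."""
    return 100.0 - expected_misclassified_percent(k_sd)
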