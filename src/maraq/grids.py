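"""Core voxel-grid containers.

Everything downstream (segmentation, metrics, the pipeline) operates on these
three containers.  Axis order is ``(z, y, x)`` with 0-based indices; physical
coordinates and spacings are in millimetres.  All pairwise operations between
grids require *identical* shape and spacing — there is deliberately no
resampling or registration anywhere in this package: co-registration is
assumed to come from acquiring every series in the exact same position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridInfo", "VoxelVolume", "RegionMask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


@dataclass(frozen=True)
class GridInfo:
    """Geometry of a voxel grid: shape, spacing and origin, axis order (z, y, x)."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing_mm) != 3:
            raise ValueError("GridInfo is strictly 3-D (z, y, x)")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def compatible_with(self, other: "GridInfo") -> bool:
        """Shape and spacing match (origin is informational only)."""
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm, rtol=1e-6, atol=1e-6
        )

    def require_same(self, other: "GridInfo", what: str = "operands") -> None:
        if not self.compatible_with(other):
            raise GridMismatchError(
                f"{what} live on different grids: "
                f"{self.shape}@{self.spacing_mm} vs {other.shape}@{other.spacing_mm}"
            )

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centres."""
        return tuple(
            o + np.arange(n) * s
            for n, s, o in zip(self.shape, self.spacing_mm, self.origin_mm)
        )


@dataclass
class VoxelVolume:
    """A 3-D scalar image in Hounsfield units on a known grid."""

    data: np.ndarray
    grid: GridInfo

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.data.ndim}-D")
        if tuple(self.data.shape) != self.grid.shape:
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        spacing_mm: tuple[float, float, float],
        origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VoxelVolume":
        data = np.asarray(data)
        return cls(data, GridInfo(tuple(data.shape), tuple(spacing_mm), tuple(origin_mm)))

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.grid)


@dataclass
class RegionMask:
    """A binary region on the same grid as the image it refers to.

    Masks are strictly binary; fractional / partial-volume masks are not
    supported.
    """

    data: np.ndarray
    grid: GridInfo

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {self.data.ndim}-D")
        if tuple(self.data.shape) != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        spacing_mm: tuple[float, float, float],
        origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "RegionMask":
        data = np.asarray(data)
        return cls(data, GridInfo(tuple(data.shape), tuple(spacing_mm), tuple(origin_mm)))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    def intersect(self, other: "RegionMask") -> "RegionMask":
        self.grid.require_same(other.grid, "masks")
        return RegionMask(self.data & other.data, self.grid)

    def copy(self) -> "RegionMask":
        return RegionMask(self.data.copy(), self.grid)
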