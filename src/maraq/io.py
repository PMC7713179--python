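"""Volume/mask/config I/O with strict grid-consistency checking.

Volumes and masks are NIfTI files: HU as signed 16-bit, label maps and masks
as unsigned 8-bit, voxel spacing in the header.  In memory the package uses
axis order (z, y, x); NIfTI stores (x, y, z), so arrays are transposed on
the way in and out.  Study configurations are YAML; results tables are
CSV/JSON (written by the pipeline).

This is also where grid consistency is enforced for file-borne inputs: a
mask whose grid differs from its image is rejected by
``GridInfo.require_same`` downstream — there is no resampling anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import GridInfo, RegionMask, VoxelVolume
from .tables import MATERIALS, PROTOCOL_STATS

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "SeriesConfig", "StudyConfig", "load_config", "ConfigError",
]

DEFAULT_MARGINS_MM = {"cortical_bone": 2.0, "bone_marrow": 2.0, "water": 30.0}


class ConfigError(ValueError):
    """Invalid or inconsistent study configuration."""


def _grid_from_nifti(img: nib.Nifti1Image) -> GridInfo:
    if img.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {img.ndim}-D")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    origin = img.affine[:3, 3]  # (x, y, z)
    shape = img.shape  # (x, y, z)
    return GridInfo(
        shape=(int(shape[2]), int(shape[1]), int(shape[0])),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin_mm=(float(origin[2]), float(origin[1]), float(origin[0])),
    )


def _affine(grid: GridInfo) -> np.ndarray:
    aff = np.diag([grid.spacing_mm[2], grid.spacing_mm[1], grid.spacing_mm[0], 1.0])
    aff[:3, 3] = [grid.origin_mm[2], grid.origin_mm[1], grid.origin_mm[0]]
    return aff


def read_volume(path: str | Path) -> VoxelVolume:
    """Load a NIfTI volume as HU with its grid; must be 3-D."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    grid = _grid_from_nifti(img)
    data = np.asanyarray(img.dataobj).astype(np.float32).T  # (x,y,z) -> (z,y,x)
    return VoxelVolume(data, grid)


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write HU as int16 NIfTI (values rounded to the nearest integer HU)."""
    data = np.round(np.asarray(vol.data)).astype(np.int16).T  # (z,y,x) -> (x,y,z)
    nib.save(nib.Nifti1Image(data, _affine(vol.grid)), str(path))


def read_mask(path: str | Path) -> RegionMask:
    """Load a binary NIfTI mask (any non-zero voxel is inside)."""
    vol = read_volume(path)
    return RegionMask(vol.data != 0, vol.grid)


def write_mask(mask: RegionMask, path: str | Path) -> None:
    data = mask.data.astype(np.uint8).T
    nib.save(nib.Nifti1Image(data, _affine(mask.grid)), str(path))


# ---------------------------------------------------------------------------
# study configuration


@dataclass(frozen=True)
class SeriesConfig:
    """One CT series of the study.

    Either names a published protocol (material means/SDs filled from the
    table) or spells out detector/mode/kVp/keV itself.  Paths are only
    needed when the study runs on files instead of simulation.
    """

    id: str
    protocol: str | None = None
    detector: str | None = None
    mode: str | None = None
    kvp: int | None = None
    kev: int | None = None
    phantom_path: str | None = None
    water_only_path: str | None = None
    noise_sigma_hu: float | None = None
    ctdi_mgy: float | None = None  # dose metadata only; no computational role

    def resolved_detector(self) -> str:
        if self.detector:
            return self.detector
        if self.protocol:
            return "EID" if self.protocol.startswith("EID") else "PCD"
        raise ConfigError(f"series {self.id!r}: detector unspecified")

    def resolved_kvp(self) -> int:
        if self.kvp:
            return int(self.kvp)
        if self.protocol and self.protocol in PROTOCOL_STATS:
            from .tables import PROTOCOL_ACQUISITION
            return int(PROTOCOL_ACQUISITION[self.protocol]["kvp"])
        raise ConfigError(f"series {self.id!r}: tube potential unspecified")


@dataclass
class StudyConfig:
    """Validated study description: series, materials, margins, thresholds."""

    series: list[SeriesConfig]
    materials: list[str] = field(default_factory=lambda: list(MATERIALS))
    margins_mm: dict = field(default_factory=lambda: dict(DEFAULT_MARGINS_MM))
    k_sd: float = 3.0
    threshold_source: str = "eid"  # "eid": same-kVp EID reference; "self": own series
    seed: int = 0
    simulate: bool = True
    phantom: dict = field(default_factory=dict)  # PhantomSpec field overrides
    artifacts: dict | None = None  # inject_artifacts kwargs (global or per-series)
    reference_mask_paths: dict = field(default_factory=dict)  # material -> path
    voi_mask_paths: dict = field(default_factory=dict)  # material -> path

    def __post_init__(self) -> None:
        ids = [s.id for s in self.series]
        if not ids:
            raise ConfigError("study needs at least one series")
        if len(set(ids)) != len(ids):
            raise ConfigError("series ids must be unique")
        if self.k_sd <= 0:
            raise ConfigError("k_sd must be > 0")
        unknown = [m for m in self.materials if m not in MATERIALS]
        if unknown:
            raise ConfigError(f"unknown materials {unknown}; known: {list(MATERIALS)}")
        if self.threshold_source not in ("eid", "self"):
            raise ConfigError("threshold_source must be 'eid' or 'self'")
        for m in self.materials:
            self.margins_mm.setdefault(m, DEFAULT_MARGINS_MM[m])
        if self.threshold_source == "eid":
            eid_kvps = {s.resolved_kvp() for s in self.series
                        if s.resolved_detector() == "EID"}
            for s in self.series:
                if s.resolved_detector() == "PCD" and s.resolved_kvp() not in eid_kvps:
                    raise ConfigError(
                        f"PCD series {s.id!r} at {s.resolved_kvp()} kVp has no "
                        f"same-kVp EID series to derive thresholds from"
                    )

    def threshold_source_id(self, series_id: str) -> str:
        """Which series supplies the thresholds applied to ``series_id``."""
        by_id = {s.id: s for s in self.series}
        s = by_id[series_id]
        if self.threshold_source == "self" or s.resolved_detector() == "EID":
            return series_id
        kvp = s.resolved_kvp()
        for other in self.series:
            if other.resolved_detector() == "EID" and other.resolved_kvp() == kvp:
                return other.id
        raise ConfigError(f"no EID reference series for {series_id!r}")


def load_config(path: str | Path) -> StudyConfig:
    """Parse and validate a YAML study configuration, filling defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "series" not in raw:
        raise ConfigError("config must be a mapping with a 'series' list")
    series = [SeriesConfig(**entry) for entry in raw.pop("series")]
    return StudyConfig(series=series, **raw)
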