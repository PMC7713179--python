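"""Synthetic hip-prosthesis phantom generator.

Emulates a physical phantom used for metal-artifact studies: a tapered metal
femoral stem (titanium-like) embedded in a foam femur model (cortical shell
around a marrow core), submerged in a rectangular water bath (13 cm high,
22 cm wide).  The proximal portion of the volume (the femoral shaft holding
the stem) is where artifacts are quantified; an artifact-free reference
region sits at the distal end, separated by a guard gap of at least 10 cm.

The simulator does not model CT physics.  Each material is painted at its
published mean CT number, streak artifacts are injected as analytic
alternating hyper-/hypo-dense angular rays decaying with distance from the
stem, and image noise is additive Gaussian in HU with the published water-SD
magnitudes.  This is sufficient to exercise every stage of the threshold
segmentation pipeline against a known ground truth, which real scans cannot
provide.

Axis order (z, y, x); z index 0 is the proximal end of the phantom.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .grids import GridInfo, RegionMask, VoxelVolume
from .tables import MATERIALS, PROTOCOL_ACQUISITION, PROTOCOL_STATS

__all__ = [
    "AIR", "WATER", "CORTICAL", "MARROW", "METAL", "LABEL_NAMES",
    "PhantomSpec", "AcquisitionProtocol", "LabeledVolume", "SimulatedSeries",
    "build_phantom", "inject_artifacts", "add_noise",
    "simulate_detector_noise", "simulate_acquisition_set",
    "calibrate_truth_fraction", "reference_mask", "voi_mask",
    "slice_truth_profile", "subseed",
]

# label ids
AIR, WATER, CORTICAL, MARROW, METAL = 0, 1, 2, 3, 4
LABEL_NAMES = {AIR: "air", WATER: "water", CORTICAL: "cortical_bone",
               MARROW: "bone_marrow", METAL: "metal"}
MATERIAL_LABELS = {"water": WATER, "cortical_bone": CORTICAL, "bone_marrow": MARROW}

AIR_HU = -1000.0


def subseed(seed: int, tag: str) -> int:
    """Stable fan-out of one study seed into independent per-stage seeds."""
    return zlib.crc32(f"{int(seed)}:{tag}".encode()) & 0x7FFFFFFF


class InvalidSpecError(ValueError):
    """Phantom geometry that cannot be realised (e.g. stem wider than marrow)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic phantom, lengths in mm.

    Stem and femur cross sections are ellipses; ``*_axes_mm`` are full
    diameters ``(x, y)`` as conventionally quoted, ``femur_outer_radii_mm``
    are semi-axes ``(x, y)``.  The stem tapers linearly from its proximal to
    its distal cross section over ``stem_length_mm``.
    """

    bath_width_mm: float = 220.0
    bath_height_mm: float = 130.0
    femur_outer_radii_mm: tuple[float, float] = (36.0, 30.0)
    cortical_thickness_mm: float = 5.0
    stem_proximal_axes_mm: tuple[float, float] = (50.0, 40.0)
    stem_distal_axes_mm: tuple[float, float] = (32.0, 36.0)
    stem_length_mm: float = 85.0
    voi_length_mm: float = 90.0
    reference_length_mm: float = 72.0
    reference_gap_mm: float = 100.0
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 0.5, 0.5)  # (z, y, x)
    air_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        # YAML configs hand in lists; normalise the pair/triple fields
        for f in ("femur_outer_radii_mm", "stem_proximal_axes_mm",
                  "stem_distal_axes_mm", "voxel_spacing_mm"):
            object.__setattr__(self, f, tuple(float(v) for v in getattr(self, f)))
        lengths = (
            self.bath_width_mm, self.bath_height_mm, self.cortical_thickness_mm,
            self.stem_length_mm, self.voi_length_mm, self.reference_length_mm,
            self.reference_gap_mm, *self.femur_outer_radii_mm,
            *self.stem_proximal_axes_mm, *self.stem_distal_axes_mm,
            *self.voxel_spacing_mm,
        )
        if any(v <= 0 for v in lengths):
            raise InvalidSpecError("all phantom lengths must be > 0")
        mx, my = self.marrow_radii_mm
        for ax, ay in (self.stem_proximal_axes_mm, self.stem_distal_axes_mm):
            if ax / 2 >= mx or ay / 2 >= my:
                raise InvalidSpecError(
                    f"stem cross-section {ax}x{ay} mm does not fit inside the "
                    f"marrow cavity (semi-axes {mx}x{my} mm)"
                )
        fx, fy = self.femur_outer_radii_mm
        if 2 * fx >= self.bath_width_mm or 2 * fy >= self.bath_height_mm:
            raise InvalidSpecError("femur does not fit inside the water bath")
        if self.stem_length_mm > self.voi_length_mm:
            raise InvalidSpecError("stem must lie within the VOI z-range")

    @property
    def marrow_radii_mm(self) -> tuple[float, float]:
        fx, fy = self.femur_outer_radii_mm
        return fx - self.cortical_thickness_mm, fy - self.cortical_thickness_mm

    @property
    def z_extent_mm(self) -> float:
        return self.voi_length_mm + self.reference_gap_mm + self.reference_length_mm

    @property
    def grid(self) -> GridInfo:
        dz, dy, dx = self.voxel_spacing_mm
        nz = int(np.ceil(self.z_extent_mm / dz))
        ny = int(np.ceil((self.bath_height_mm + 2 * self.air_margin_mm) / dy))
        nx = int(np.ceil((self.bath_width_mm + 2 * self.air_margin_mm) / dx))
        return GridInfo((nz, ny, nx), (dz, dy, dx))

    @classmethod
    def coarse(cls, **overrides) -> "PhantomSpec":
        """Same physical phantom on a coarser grid — for fast experiments."""
        overrides.setdefault("voxel_spacing_mm", (4.0, 1.5, 1.5))
        return cls(**overrides)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One acquisition setting: detector, mode, tube potential, energy threshold.

    ``material_means_hu``/``material_sds_hu`` must cover cortical_bone,
    bone_marrow and water (bath with phantom).  ``water_only_*`` describe the
    companion scan of the bath alone; they fall back to the with-phantom water
    values if unset.  The prosthesis CT number is a plumbing constant: it only
    needs to exceed every plausible threshold.
    """

    name: str
    detector: str  # "EID" | "PCD"
    mode: str | None = None  # "Macro" | "Chess" for PCD
    tube_potential_kvp: int = 140
    energy_threshold_kev: int | None = None
    material_means_hu: dict = field(default_factory=dict)
    material_sds_hu: dict = field(default_factory=dict)
    water_only_mean_hu: float | None = None
    water_only_sd_hu: float | None = None
    metal_hu: float = 3000.0
    ctdi_mgy: float | None = None

    def __post_init__(self) -> None:
        if self.detector not in ("EID", "PCD"):
            raise ValueError(f"unknown detector {self.detector!r}")
        if self.detector == "PCD":
            if self.mode not in ("Macro", "Chess"):
                raise ValueError("PCD protocols require mode 'Macro' or 'Chess'")
            if self.energy_threshold_kev is None:
                raise ValueError("PCD protocols require an energy threshold [keV]")
        else:
            if self.mode not in (None, "none"):
                raise ValueError("EID protocols have no acquisition mode")
            if self.energy_threshold_kev is not None:
                raise ValueError("EID protocols have no energy threshold")
            object.__setattr__(self, "mode", None)
        if self.tube_potential_kvp not in (100, 120, 140):
            raise ValueError("tube potential must be one of 100, 120, 140 kVp")
        missing = [m for m in MATERIALS if m not in self.material_means_hu
                   or m not in self.material_sds_hu]
        if missing:
            raise ValueError(f"material map incomplete, missing {missing}")

    @classmethod
    def from_table(cls, key: str, **overrides) -> "AcquisitionProtocol":
        """Build a protocol from the published acquisition/statistics tables.

        ``overrides`` replace any field, e.g. ``name="series1"`` to relabel.
        """
        if key not in PROTOCOL_STATS:
            raise KeyError(f"unknown protocol {key!r}; known: {sorted(PROTOCOL_STATS)}")
        stats = PROTOCOL_STATS[key]
        acq = PROTOCOL_ACQUISITION[key]
        kwargs = dict(
            name=key,
            detector=acq["detector"],
            mode=acq["mode"],
            tube_potential_kvp=acq["kvp"],
            energy_threshold_kev=acq["kev"],
            material_means_hu={m: stats[m][0] for m in MATERIALS},
            material_sds_hu={m: stats[m][1] for m in MATERIALS},
            water_only_mean_hu=stats["water_only"][0],
            water_only_sd_hu=stats["water_only"][1],
            ctdi_mgy=acq["ctdi_mgy"],
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def noise_sigma_hu(self) -> float | None:
        """Image-noise magnitude used for the phantom series (water SD).

        None when the protocol carries no water SD — the acquisition-set
        simulator then falls back to sqrt(2) x the matching Macro sigma for
        Chess protocols.
        """
        sd = self.material_sds_hu["water"]
        return None if sd is None else float(sd)

    @property
    def water_only_sigma_hu(self) -> float | None:
        if self.water_only_sd_hu is not None:
            return float(self.water_only_sd_hu)
        return self.noise_sigma_hu


@dataclass
class LabeledVolume:
    """A simulated CT series with its material label map and artifact truth."""

    image: VoxelVolume
    labels: np.ndarray  # integer material id per voxel, same shape
    artifact_truth: RegionMask
    seed: int = 0
    spec: PhantomSpec | None = None
    protocol: AcquisitionProtocol | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if tuple(self.labels.shape) != self.image.grid.shape:
            raise ValueError("labels shape differs from image grid")
        self.image.grid.require_same(self.artifact_truth.grid, "image and artifact truth")

    @property
    def grid(self) -> GridInfo:
        return self.image.grid

    def material_mask(self, material: str) -> RegionMask:
        if material not in MATERIAL_LABELS:
            raise KeyError(f"unknown material {material!r}")
        return RegionMask(self.labels == MATERIAL_LABELS[material], self.grid)

    def has_metal(self) -> bool:
        return bool((self.labels == METAL).any())


@dataclass
class SimulatedSeries:
    """Co-registered pair for one protocol: phantom scan + water-only scan."""

    protocol: AcquisitionProtocol
    phantom: LabeledVolume
    water_only: LabeledVolume


# ---------------------------------------------------------------------------
# geometry helpers

def _plane_offsets(grid: GridInfo, spec: PhantomSpec):
    """In-plane physical offsets (dy, dx) of voxel centres from the bath centre."""
    _, ys, xs = grid.coordinates_mm()
    cy = spec.air_margin_mm + spec.bath_height_mm / 2
    cx = spec.air_margin_mm + spec.bath_width_mm / 2
    return ys - cy, xs - cx


def _stem_tip_z_mm(spec: PhantomSpec) -> float:
    return spec.stem_length_mm


def build_phantom(spec: PhantomSpec, protocol: AcquisitionProtocol) -> LabeledVolume:
    """Noiseless, artifact-free phantom: every voxel at its material's mean HU.

    Labels mark air, water, cortical bone, bone marrow and the metal stem;
    the artifact-truth mask is empty.
    """
    grid = spec.grid
    nz, ny, nx = grid.shape
    dy, dx = _plane_offsets(grid, spec)
    zs = grid.coordinates_mm()[0]

    labels = np.zeros(grid.shape, dtype=np.uint8)  # air

    in_bath = (
        (np.abs(dy) <= spec.bath_height_mm / 2)[:, None]
        & (np.abs(dx) <= spec.bath_width_mm / 2)[None, :]
    )
    fx, fy = spec.femur_outer_radii_mm
    mx, my = spec.marrow_radii_mm
    r2_outer = (dx[None, :] / fx) ** 2 + (dy[:, None] / fy) ** 2
    r2_marrow = (dx[None, :] / mx) ** 2 + (dy[:, None] / my) ** 2

    plane = np.zeros((ny, nx), dtype=np.uint8)
    plane[in_bath] = WATER
    plane[r2_outer <= 1.0] = CORTICAL
    plane[r2_marrow <= 1.0] = MARROW
    labels[:] = plane[None, :, :]

    # tapered metal stem: linear interpolation of semi-axes over its length
    px, py = spec.stem_proximal_axes_mm[0] / 2, spec.stem_proximal_axes_mm[1] / 2
    qx, qy = spec.stem_distal_axes_mm[0] / 2, spec.stem_distal_axes_mm[1] / 2
    for iz in np.nonzero(zs <= spec.stem_length_mm)[0]:
        t = zs[iz] / spec.stem_length_mm
        sx, sy = px + t * (qx - px), py + t * (qy - py)
        stem = (dx[None, :] / sx) ** 2 + (dy[:, None] / sy) ** 2 <= 1.0
        labels[iz][stem] = METAL

    hu_of = {
        AIR: AIR_HU,
        WATER: protocol.material_means_hu["water"],
        CORTICAL: protocol.material_means_hu["cortical_bone"],
        MARROW: protocol.material_means_hu["bone_marrow"],
        METAL: protocol.metal_hu,
    }
    lut = np.array([hu_of[i] for i in range(5)], dtype=np.float32)
    image = VoxelVolume(lut[labels], grid)
    truth = RegionMask(np.zeros(grid.shape, dtype=bool), grid)
    return LabeledVolume(image, labels, truth, seed=0, spec=spec, protocol=protocol)


def build_water_bath(spec: PhantomSpec, protocol: AcquisitionProtocol) -> LabeledVolume:
    """Companion scan: the water bath alone, no phantom inside."""
    grid = spec.grid
    dy, dx = _plane_offsets(grid, spec)
    in_bath = (
        (np.abs(dy) <= spec.bath_height_mm / 2)[:, None]
        & (np.abs(dx) <= spec.bath_width_mm / 2)[None, :]
    )
    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[:, in_bath] = WATER
    mean = (protocol.water_only_mean_hu
            if protocol.water_only_mean_hu is not None
            else protocol.material_means_hu["water"])
    image = np.full(grid.shape, AIR_HU, dtype=np.float32)
    image[:, in_bath] = mean
    truth = RegionMask(np.zeros(grid.shape, dtype=bool), grid)
    return LabeledVolume(VoxelVolume(image, grid), labels, truth,
                         seed=0, spec=spec, protocol=protocol)


# ---------------------------------------------------------------------------
# streak artifacts

def _streak_geometry(vol: LabeledVolume):
    """Per-voxel (distance to stem axis segment [mm], in-plane angle [rad])."""
    spec = vol.spec
    if spec is None:
        raise ValueError("volume carries no phantom spec; build it with build_phantom")
    grid = vol.grid
    dy, dx = _plane_offsets(grid, spec)
    zs = grid.coordinates_mm()[0]
    r = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2)  # (ny, nx)
    theta = np.arctan2(dy[:, None], dx[None, :])
    dz = np.maximum(zs - _stem_tip_z_mm(spec), 0.0)  # axis segment runs z in [0, tip]
    d = np.sqrt(r[None, :, :] ** 2 + (dz ** 2)[:, None, None])
    return d, theta


#: exponent of the generalised-Gaussian angular ray profile; higher = sharper
#: ray edges (less perturbation mass lingering near the truth cutoff).
PROFILE_POWER = 6

#: slow azimuthal twist of the ray pattern along z [rad/mm], used by the
#: calibrated experiments: it decorrelates the voxelised ray positions between
#: slices so ground-truth fractions vary smoothly with the ray width instead
#: of in column-sized jumps.  The plain default (no twist) keeps every metal
#: slice's pattern identical, making the slice-wise truth profile exactly
#: non-increasing away from the stem tip.
SMOOTHING_TWIST_RAD_PER_MM = 0.003


def _ray_angular_term(theta, z_mm, theta0, n_streaks, ray_width_rad,
                      twist_rad_per_mm, signed=True):
    """Signed angular weight of the nearest ray for voxels at angle ``theta``
    in the slice at ``z_mm``."""
    step = 2 * np.pi / n_streaks
    t0 = theta0 + twist_rad_per_mm * z_mm
    k = np.round((theta - t0) / step)
    dtheta = theta - (t0 + k * step)
    weight = np.exp(-np.abs(dtheta / ray_width_rad) ** PROFILE_POWER)
    if signed:
        weight = np.where(k.astype(np.int64) % 2 == 0, weight, -weight)
    return weight


def _streak_field(
    d: np.ndarray,
    theta: np.ndarray,
    zs_mm: np.ndarray,
    *,
    n_streaks: int,
    amplitude_hu: float,
    decay_mm: float,
    ray_width_rad: float,
    theta0: float,
    support_mm: float,
    twist_rad_per_mm: float,
    tip_z_mm: float,
) -> np.ndarray:
    """Analytic perturbation: alternating angular rays with radial decay.

    Each voxel is attributed to its nearest ray; rays alternate in sign and
    have a steep generalised-Gaussian angular profile so the perturbation
    transitions sharply at ray edges.  Amplitude decays as 1/(1 + d/decay)
    and is truncated to zero beyond ``support_mm`` so distant regions (the
    artifact-free reference) stay untouched.

    The ray pattern's twist is frozen beyond the stem tip: distal slices see
    the tip slice's pattern attenuated by the growing 3-D distance, so the
    per-slice truth sets are nested (strictly shrinking) past the tip.
    """
    out = np.empty(d.shape, dtype=np.float32)
    for iz in range(d.shape[0]):
        envelope = (amplitude_hu / (1.0 + d[iz] / decay_mm)).astype(np.float32)
        envelope[d[iz] > support_mm] = 0.0
        z_eff = min(float(zs_mm[iz]), tip_z_mm)
        angular = _ray_angular_term(theta, z_eff, theta0, n_streaks,
                                    ray_width_rad, twist_rad_per_mm)
        out[iz] = envelope * angular.astype(np.float32)
    return out


def _applicable_region(vol: LabeledVolume) -> np.ndarray:
    """Voxels the streak perturbation may touch.

    Tissue and water only — never air, the prosthesis itself, or the
    prosthesis' axial footprint (the in-plane union of all stem cross
    sections, extended along z).  Keeping the footprint cylinder clean makes
    the per-slice truth statistics vary smoothly along z: they are driven by
    the radial decay, not by the changing metal cross-section.
    """
    spec = vol.spec
    grid = vol.grid
    dy, dx = _plane_offsets(grid, spec)
    fx = max(spec.stem_proximal_axes_mm[0], spec.stem_distal_axes_mm[0]) / 2
    fy = max(spec.stem_proximal_axes_mm[1], spec.stem_distal_axes_mm[1]) / 2
    footprint = (dx[None, :] / fx) ** 2 + (dy[:, None] / fy) ** 2 <= 1.0
    applicable = (vol.labels != METAL) & (vol.labels != AIR)
    applicable &= ~footprint[None, :, :]
    return applicable


def inject_artifacts(
    vol: LabeledVolume,
    n_streaks: int = 24,
    amplitude_hu: float = 600.0,
    decay_mm: float = 20.0,
    truth_cutoff_hu: float = 150.0,
    seed: int = 0,
    *,
    ray_width_rad: float | None = None,
    support_mm: float | None = None,
    twist_rad_per_mm: float = 0.0,
) -> LabeledVolume:
    """Add streak artifacts around the metal stem and record their ground truth.

    The perturbation is applied to tissue and water voxels only (the
    prosthesis itself and surrounding air are left unchanged).  Ground truth
    is the set of voxels whose injected perturbation exceeds
    ``truth_cutoff_hu`` in magnitude.
    """
    if not vol.has_metal():
        raise ValueError("volume contains no metal; nothing to emanate streaks from")
    if vol.artifact_truth.n_voxels:
        raise ValueError("volume already carries injected artifacts")
    if amplitude_hu < 0 or truth_cutoff_hu < 0:
        raise ValueError("amplitude and truth cutoff must be non-negative")
    if amplitude_hu and amplitude_hu <= truth_cutoff_hu:
        raise ValueError("amplitude_hu must exceed truth_cutoff_hu")
    if n_streaks < 2 or n_streaks % 2:
        raise ValueError("n_streaks must be an even count >= 2 (alternating signs)")

    out = LabeledVolume(vol.image.copy(), vol.labels, vol.artifact_truth.copy(),
                        seed=seed, spec=vol.spec, protocol=vol.protocol)
    if amplitude_hu == 0:
        return out

    rng = np.random.default_rng(seed)
    theta0 = float(rng.uniform(0, 2 * np.pi / n_streaks))
    if ray_width_rad is None:
        ray_width_rad = 0.2 * (2 * np.pi / n_streaks)
    if support_mm is None:
        # never let streaks reach the artifact-free reference zone
        support_mm = min(4.0 * decay_mm, 0.9 * vol.spec.reference_gap_mm)

    d, theta = _streak_geometry(vol)
    pert = _streak_field(
        d, theta, vol.grid.coordinates_mm()[0],
        n_streaks=n_streaks, amplitude_hu=amplitude_hu,
        decay_mm=decay_mm, ray_width_rad=ray_width_rad, theta0=theta0,
        support_mm=support_mm, twist_rad_per_mm=twist_rad_per_mm,
        tip_z_mm=_stem_tip_z_mm(vol.spec),
    )
    pert = np.where(_applicable_region(vol), pert, 0.0).astype(np.float32)

    out.image.data = out.image.data + pert
    out.artifact_truth = RegionMask(np.abs(pert) > truth_cutoff_hu, vol.grid)
    return out


def calibrate_truth_fraction(
    vol: LabeledVolume,
    voi: RegionMask,
    target_percent: float,
    *,
    n_streaks: int = 24,
    amplitude_hu: float,
    decay_mm: float,
    truth_cutoff_hu: float,
    seed: int = 0,
    support_mm: float | None = None,
    twist_rad_per_mm: float = 0.0,
    tol_percent: float = 0.02,
) -> float:
    """Ray half-width that yields a given ground-truth artifact percentage.

    The truth fraction inside the VOI grows monotonically with the angular
    ray width, so a bisection on the noiseless perturbation field pins the
    width that hits ``target_percent``.  Returns the calibrated
    ``ray_width_rad`` to pass to :func:`inject_artifacts` (with the same
    seed and streak parameters).
    """
    if not 0 < target_percent < 100:
        raise ValueError("target_percent must be in (0, 100)")
    vol.grid.require_same(voi.grid, "volume and VOI")
    rng = np.random.default_rng(seed)
    theta0 = float(rng.uniform(0, 2 * np.pi / n_streaks))
    if support_mm is None:
        support_mm = 4.0 * decay_mm

    d, theta = _streak_geometry(vol)
    sel = voi.data & _applicable_region(vol)
    if not sel.any():
        raise ValueError("VOI selects no applicable voxels")
    iz, iy, ix = np.nonzero(sel)
    d_sel = d[iz, iy, ix]
    theta_sel = theta[iy, ix]
    tip = _stem_tip_z_mm(vol.spec)
    z_sel = np.minimum(vol.grid.coordinates_mm()[0][iz], tip)
    n_voi = int(voi.data.sum())

    envelope = amplitude_hu / (1.0 + d_sel / decay_mm)
    envelope[d_sel > support_mm] = 0.0

    def frac(w: float) -> float:
        weight = _ray_angular_term(theta_sel, z_sel, theta0, n_streaks, w,
                                   twist_rad_per_mm, signed=False)
        return 100.0 * float((envelope * weight > truth_cutoff_hu).sum()) / n_voi

    lo, hi = 1e-5, 0.45 * (2 * np.pi / n_streaks)
    if frac(hi) < target_percent:
        raise ValueError(
            f"target {target_percent}% unreachable: max attainable "
            f"{frac(hi):.2f}% with {n_streaks} streaks at this amplitude/decay"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target_percent:
            lo = mid
        else:
            hi = mid
        if abs(frac(hi) - target_percent) <= tol_percent:
            break
    return hi


def slice_truth_profile(vol: LabeledVolume) -> list[tuple[float, float]]:
    """Mean slice-wise artifact-truth fraction vs |z - stem tip| in mm.

    Slices are grouped by their absolute z-distance to the stem tip and the
    truth fraction (over all voxels of the slice) averaged per group; the
    result is sorted by distance.
    """
    if vol.spec is None:
        raise ValueError("volume carries no phantom spec")
    dz = vol.grid.spacing_mm[0]
    zs = vol.grid.coordinates_mm()[0]
    tip_slice = int(np.argmin(np.abs(zs - _stem_tip_z_mm(vol.spec))))
    frac = vol.artifact_truth.data.reshape(vol.grid.shape[0], -1).mean(axis=1)
    out: dict[float, list[float]] = {}
    for iz, fi in enumerate(frac):
        out.setdefault(abs(iz - tip_slice) * dz, []).append(float(fi))
    return sorted((d, float(np.mean(f))) for d, f in out.items())


# ---------------------------------------------------------------------------
# noise

def add_noise(vol: LabeledVolume, sigma_hu: float, seed: int = 0) -> LabeledVolume:
    """Additive zero-mean Gaussian noise in HU; labels and truth unchanged."""
    if sigma_hu < 0:
        raise ValueError("sigma_hu must be >= 0")
    out = LabeledVolume(vol.image.copy(), vol.labels, vol.artifact_truth.copy(),
                        seed=seed, spec=vol.spec, protocol=vol.protocol)
    if sigma_hu == 0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(vol.grid.shape, dtype=np.float32) * np.float32(sigma_hu)
    out.image.data = out.image.data + noise
    return out


def simulate_detector_noise(n_subpixels_used: int, n_samples: int, seed: int = 0) -> float:
    """Empirical image-noise SD when each pixel averages N unit-variance subpixels.

    A Macro-mode pixel averages all 16 subpixels of the 4x4 tile; a Chess-mode
    threshold setting only sees half of them.  The per-pixel mean of
    ``n_subpixels_used`` independent unit-variance samples has SD
    1/sqrt(n_subpixels_used), so halving the subpixels raises noise by
    sqrt(2).
    """
    if n_subpixels_used < 1:
        raise ValueError("n_subpixels_used must be >= 1")
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a stable SD estimate")
    rng = np.random.default_rng(seed)
    pixel_means = rng.standard_normal((n_samples, n_subpixels_used)).mean(axis=1)
    return float(np.std(pixel_means, ddof=1))


# ---------------------------------------------------------------------------
# full acquisition sets

def _resolve_sigma(protocol: AcquisitionProtocol,
                   protocols: list[AcquisitionProtocol],
                   which: str) -> float:
    """Noise sigma for a series; a Chess protocol without its own SD defaults
    to sqrt(2) x the sigma of the same-kVp/keV Macro protocol in the set."""
    sigma = (protocol.noise_sigma_hu if which == "phantom"
             else protocol.water_only_sigma_hu)
    if sigma is not None and sigma > 0:
        return sigma
    if protocol.mode == "Chess":
        for other in protocols:
            if (other.mode == "Macro"
                    and other.tube_potential_kvp == protocol.tube_potential_kvp
                    and other.energy_threshold_kev == protocol.energy_threshold_kev):
                base = (other.noise_sigma_hu if which == "phantom"
                        else other.water_only_sigma_hu)
                return float(np.sqrt(2.0) * base)
    raise ValueError(f"no noise sigma available for protocol {protocol.name!r}")


def simulate_acquisition_set(
    spec: PhantomSpec,
    protocols: list[AcquisitionProtocol],
    artifact_params: dict | None = None,
    seed: int = 0,
) -> dict[str, SimulatedSeries]:
    """Co-registered series for every protocol, each with a water-only companion.

    All series share one grid (``spec.grid``), so a VOI drawn on one series
    applies verbatim to every other.  The streak pattern is generated from a
    seed shared across protocols — every series shows the same artifact
    geometry, as physical series of one phantom would — while the noise seed
    differs per series.

    ``artifact_params`` are keyword arguments for :func:`inject_artifacts`,
    either one dict for all series or a mapping protocol-name -> dict; None
    disables artifact injection.
    """
    if not protocols:
        raise ValueError("at least one protocol is required")
    names = [p.name for p in protocols]
    if len(set(names)) != len(names):
        raise ValueError("protocol names must be unique")

    streak_seed = subseed(seed, "streaks")
    out: dict[str, SimulatedSeries] = {}
    for protocol in protocols:
        vol = build_phantom(spec, protocol)
        params = artifact_params
        if params is not None and any(k in params for k in names):
            params = params.get(protocol.name)
        if params:
            vol = inject_artifacts(vol, seed=streak_seed, **params)
        sigma = _resolve_sigma(protocol, protocols, "phantom")
        vol = add_noise(vol, sigma, seed=subseed(seed, f"{protocol.name}:noise"))

        bath = build_water_bath(spec, protocol)
        sigma_w = _resolve_sigma(protocol, protocols, "water_only")
        bath = add_noise(bath, sigma_w, seed=subseed(seed, f"{protocol.name}:water"))
        out[protocol.name] = SimulatedSeries(protocol, vol, bath)
    return out


# ---------------------------------------------------------------------------
# study regions derived from the label map

def reference_mask(vol: LabeledVolume, material: str,
                   margin_mm: float = 0.0) -> RegionMask:
    """Artifact-free reference region: distal z-window, margin-eroded material.

    The material mask is metrically eroded over the full volume first (so
    margins act toward neighbouring materials, not toward the z-crop), then
    intersected with the distal reference window.
    """
    from .segmentation import erode_mask_mm  # local import to avoid cycle

    spec = vol.spec
    if spec is None:
        raise ValueError("volume carries no phantom spec")
    mask = vol.material_mask(material)
    if margin_mm > 0:
        mask = erode_mask_mm(mask, margin_mm)
    zs = vol.grid.coordinates_mm()[0]
    z_start = spec.z_extent_mm - spec.reference_length_mm
    sel = mask.data.copy()
    sel[zs < z_start, :, :] = False
    return RegionMask(sel, vol.grid)


def voi_mask(vol: LabeledVolume, material: str) -> RegionMask:
    """Volume of interest: the material compartment within the proximal
    (prosthesis-bearing) z-window."""
    spec = vol.spec
    if spec is None:
        raise ValueError("volume carries no phantom spec")
    mask = vol.material_mask(material)
    zs = vol.grid.coordinates_mm()[0]
    sel = mask.data.copy()
    sel[zs > spec.voi_length_mm, :, :] = False
    return RegionMask(sel, vol.grid)
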