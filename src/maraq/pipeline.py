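"""End-to-end study orchestration.

``run_study`` executes the whole quantification in order: obtain the series
(simulated or loaded), compute per-series reference statistics, derive
thresholds from the designated source series (the same-kVp EID acquisition
by default), propagate the VOIs drawn on the first series, segment
artifacts, apply the misclassification correction, and compute noise and
CNR.  Everything is deterministic given the configured seed; every
threshold, voxel count and percentage ends up in the result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grids import RegionMask, VoxelVolume
from .io import SeriesConfig, StudyConfig, read_mask, read_volume
from .metrics import (ArtifactResult, CnrResult, NoiseResult, artifact_fraction,
                      cnr, corrected_fraction, correction_factor,
                      distance_profile, noise)
from .phantom import (AcquisitionProtocol, PhantomSpec, reference_mask,
                      simulate_acquisition_set, voi_mask)
from .segmentation import (MaterialStats, ThresholdPair, compute_thresholds,
                           propagate_voi, region_stats, segment_artifacts)

__all__ = ["StudyResult", "run_study"]

log = logging.getLogger("maraq")


@dataclass
class StudyResult:
    """All tables a study produces, plus provenance and the working masks."""

    config: StudyConfig
    thresholds: pd.DataFrame
    artifacts: pd.DataFrame
    noise: pd.DataFrame
    cnr: pd.DataFrame
    provenance: dict
    reference_stats: dict = field(default_factory=dict)  # (series, material) -> MaterialStats
    artifact_masks: dict = field(default_factory=dict)  # (series, material) -> RegionMask
    vois: dict = field(default_factory=dict)  # material -> RegionMask
    series_truth: dict = field(default_factory=dict)  # series -> RegionMask or None

    def distance_profiles(self, reference_z: int) -> pd.DataFrame:
        """Fig.-3-style per-slice artifact percentages for every series/material."""
        rows = []
        for (sid, material), mask in self.artifact_masks.items():
            for dist, pct in distance_profile(mask, self.vois[material], reference_z):
                rows.append({"series": sid, "material": material,
                             "distance_mm": dist, "artifact_percent": pct})
        return pd.DataFrame(rows)

    def write_tables(self, outdir: str | Path) -> None:
        """Write results.csv, noise.csv, cnr.csv, thresholds.csv and study.json.

        Printed precision follows reporting convention: percentages to one
        decimal, CNR to two, HU to two.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        art = self.artifacts.copy()
        for c in ("raw_percent", "correction_percent", "corrected_percent"):
            art[c] = art[c].round(1)
        art.to_csv(outdir / "results.csv", index=False)
        nz = self.noise.copy()
        nz["noise_hu"] = nz["noise_hu"].round(2)
        nz.to_csv(outdir / "noise.csv", index=False)
        cn = self.cnr.copy()
        cn["cnr"] = cn["cnr"].round(2)
        cn.to_csv(outdir / "cnr.csv", index=False)
        th = self.thresholds.copy()
        for c in ("mean_hu", "sd_hu", "lower_hu", "upper_hu"):
            th[c] = th[c].round(2)
        th.to_csv(outdir / "thresholds.csv", index=False)
        payload = {
            "provenance": self.provenance,
            "results": art.to_dict(orient="records"),
            "noise": nz.to_dict(orient="records"),
            "cnr": cn.to_dict(orient="records"),
        }
        (outdir / "study.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _simulated_series(config: StudyConfig):
    spec = PhantomSpec(**config.phantom)
    protocols = []
    for s in config.series:
        if s.protocol is None:
            raise ValueError(
                f"series {s.id!r}: simulation requires a published protocol name"
            )
        overrides = {"name": s.id}
        if s.noise_sigma_hu is not None:
            # override applies to both the phantom and the water-only scan
            overrides["material_sds_hu"] = {
                **{m: sd for m, sd in
                   AcquisitionProtocol.from_table(s.protocol).material_sds_hu.items()},
                "water": s.noise_sigma_hu,
            }
            overrides["water_only_sd_hu"] = s.noise_sigma_hu
        protocols.append(AcquisitionProtocol.from_table(s.protocol, **overrides))
    sims = simulate_acquisition_set(spec, protocols,
                                    artifact_params=config.artifacts,
                                    seed=config.seed)
    return spec, sims


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full quantification pipeline for one study configuration."""
    by_stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            spec, sims = _simulated_series(config)
            first = sims[config.series[0].id].phantom
            ref_masks = {m: reference_mask(first, m, config.margins_mm[m])
                         for m in config.materials}
            vois_first = {m: voi_mask(first, m) for m in config.materials}
            volumes = {sid: sims[sid].phantom.image for sid in sims}
            water_only = {sid: sims[sid].water_only.image for sid in sims}
            water_only_mask = {
                sid: RegionMask(sims[sid].water_only.labels != 0,
                                sims[sid].water_only.grid)
                for sid in sims
            }
            # apply the water margin to the bath-only mask as well
            from .segmentation import erode_mask_mm
            water_only_mask = {
                sid: erode_mask_mm(mask, config.margins_mm.get("water", 30.0))
                for sid, mask in water_only_mask.items()
            }
            truth = {sid: sims[sid].phantom.artifact_truth for sid in sims}
        else:
            spec = None
            volumes, water_only, water_only_mask, truth = {}, {}, {}, {}
            for s in config.series:
                if not s.phantom_path:
                    raise ValueError(f"series {s.id!r}: phantom_path required")
                volumes[s.id] = read_volume(s.phantom_path)
                if s.water_only_path:
                    water_only[s.id] = read_volume(s.water_only_path)
            ref_masks = {m: read_mask(p)
                         for m, p in config.reference_mask_paths.items()}
            vois_first = {m: read_mask(p) for m, p in config.voi_mask_paths.items()}
            missing = [m for m in config.materials
                       if m not in ref_masks or m not in vois_first]
            if missing:
                raise ValueError(f"reference/VOI masks missing for {missing}")
            # noise mask for loaded water-only series: the water reference mask
            water_only_mask = {sid: ref_masks["water"] for sid in water_only}

        # stage 1: reference statistics, per series and material
        by_stage = "reference-stats"
        stats: dict[tuple[str, str], MaterialStats] = {}
        for s in config.series:
            for m in config.materials:
                stats[(s.id, m)] = region_stats(volumes[s.id], ref_masks[m],
                                                material=m, source_series=s.id)
                st = stats[(s.id, m)]
                log.info("stats %s/%s: mean=%.2f sd=%.2f n=%d",
                         s.id, m, st.mean_hu, st.sd_hu, st.n_voxels)

        # stage 2: thresholds from the designated source series
        by_stage = "thresholds"
        thresholds: dict[tuple[str, str], ThresholdPair] = {}
        thr_rows = []
        for s in config.series:
            src = config.threshold_source_id(s.id)
            for m in config.materials:
                st = stats[(src, m)]
                thr = compute_thresholds(st, config.k_sd,
                                         tube_potential_kvp=s.resolved_kvp())
                thresholds[(s.id, m)] = thr
                thr_rows.append({
                    "series": s.id, "material": m, "source_series": src,
                    "kvp": s.resolved_kvp(), "mean_hu": st.mean_hu,
                    "sd_hu": st.sd_hu, "k_sd": config.k_sd,
                    "lower_hu": thr.lower_hu, "upper_hu": thr.upper_hu,
                })
                log.info("thresholds %s/%s from %s: [%.2f, %.2f]",
                         s.id, m, src, thr.lower_hu, thr.upper_hu)

        # stage 3: VOI propagation (strict same-grid copy)
        by_stage = "voi-propagation"
        vois = {m: vois_first[m] for m in config.materials}
        for s in config.series:
            for m in config.materials:
                propagate_voi(vois[m], volumes[s.id])  # raises on any grid mismatch

        # stage 4+5: artifact segmentation and correction
        by_stage = "segmentation"
        art_rows, masks = [], {}
        for s in config.series:
            for m in config.materials:
                thr = thresholds[(s.id, m)]
                mask = segment_artifacts(volumes[s.id], thr, vois[m])
                raw = artifact_fraction(mask, vois[m])
                corr = correction_factor(volumes[s.id], ref_masks[m], thr)
                res = ArtifactResult(
                    series=s.id, material=m,
                    voi_voxels=vois[m].n_voxels, artifact_voxels=mask.n_voxels,
                    raw_percent=raw, correction_percent=corr,
                    corrected_percent=corrected_fraction(raw, corr),
                )
                masks[(s.id, m)] = mask
                art_rows.append(asdict(res))
                log.info("artifacts %s/%s: raw=%.2f%% corr=%.2f%% net=%.2f%%",
                         s.id, m, raw, corr, res.corrected_percent)

        # stage 6: noise and CNR
        by_stage = "metrics"
        noise_rows = []
        for s in config.series:
            if s.id in water_only:
                nr = noise(water_only[s.id], water_only_mask[s.id], series=s.id)
                noise_rows.append(asdict(nr))
        cnr_rows = []
        for s in config.series:
            water_st = stats[(s.id, "water")]
            for m in ("cortical_bone", "bone_marrow"):
                if m in config.materials:
                    cr = cnr(stats[(s.id, m)], water_st, series=s.id)
                    cnr_rows.append(asdict(cr))

        provenance = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "tool_version": __version__,
            "simulated": config.simulate,
        }
        return StudyResult(
            config=config,
            thresholds=pd.DataFrame(thr_rows),
            artifacts=pd.DataFrame(art_rows),
            noise=pd.DataFrame(noise_rows),
            cnr=pd.DataFrame(cnr_rows),
            provenance=provenance,
            reference_stats=stats,
            artifact_masks=masks,
            vois=vois,
            series_truth=truth if config.simulate else {},
        )
    except Exception as exc:
        raise RuntimeError(f"study failed in stage '{by_stage}': {exc}") from exc
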