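"""Simulator: geometry, material HU, streaks, noise, detector-mode law."""

import numpy as np
import pytest

from maraq.grids import RegionMask
from maraq.phantom import (CORTICAL, MARROW, METAL, WATER, AcquisitionProtocol,
                           InvalidSpecError, PhantomSpec, add_noise,
                           build_phantom, build_water_bath,
                           calibrate_truth_fraction, inject_artifacts,
                           simulate_acquisition_set, simulate_detector_noise,
                           slice_truth_profile, voi_mask)


class TestBuildPhantom:
    def test_materials_painted_at_published_means(self, clean_phantom):
        img, lab = clean_phantom.image.data, clean_phantom.labels
        assert np.all(img[lab == CORTICAL] == np.float32(679.70))
        assert np.all(img[lab == MARROW] == np.float32(-674.12))
        assert np.all(img[lab == WATER] == np.float32(-0.34))
        assert np.all(img[lab == METAL] == np.float32(3000.0))
        assert clean_phantom.artifact_truth.n_voxels == 0

    def test_macro_protocol_cortical_mean(self, coarse_spec, macro140):
        vol = build_phantom(coarse_spec, macro140)
        assert np.all(vol.image.data[vol.labels == CORTICAL] == np.float32(595.96))

    def test_every_material_present(self, clean_phantom):
        for lab in (WATER, CORTICAL, MARROW, METAL):
            assert (clean_phantom.labels == lab).any()

    def test_stem_wider_than_marrow_rejected(self):
        with pytest.raises(InvalidSpecError, match="marrow"):
            PhantomSpec(stem_proximal_axes_mm=(80.0, 60.0))

    def test_femur_wider_than_bath_rejected(self):
        with pytest.raises(InvalidSpecError, match="bath"):
            PhantomSpec(femur_outer_radii_mm=(120.0, 80.0),
                        bath_width_mm=220.0, bath_height_mm=130.0)

    def test_protocol_validation(self):
        with pytest.raises(ValueError, match="mode"):
            AcquisitionProtocol.from_table("Macro-HTI 140/75", mode=None)
        with pytest.raises(ValueError, match="threshold"):
            AcquisitionProtocol.from_table("Chess-HTI 140/75",
                                           energy_threshold_kev=None)
        with pytest.raises(ValueError, match="material"):
            AcquisitionProtocol(name="x", detector="EID",
                                material_means_hu={"water": 0.0},
                                material_sds_hu={"water": 30.0})


class TestInjectArtifacts:
    def test_zero_amplitude_is_identity(self, clean_phantom):
        out = inject_artifacts(clean_phantom, amplitude_hu=0.0,
                               truth_cutoff_hu=0.0, seed=1)
        np.testing.assert_array_equal(out.image.data, clean_phantom.image.data)
        assert out.artifact_truth.n_voxels == 0

    def test_deterministic_under_fixed_seed(self, clean_phantom):
        a = inject_artifacts(clean_phantom, amplitude_hu=600, truth_cutoff_hu=150,
                             decay_mm=20, seed=7)
        b = inject_artifacts(clean_phantom, amplitude_hu=600, truth_cutoff_hu=150,
                             decay_mm=20, seed=7)
        np.testing.assert_array_equal(a.artifact_truth.data, b.artifact_truth.data)
        np.testing.assert_array_equal(a.image.data, b.image.data)

    def test_requires_metal(self, coarse_spec, eid140):
        bath = build_water_bath(coarse_spec, eid140)
        with pytest.raises(ValueError, match="metal"):
            inject_artifacts(bath, amplitude_hu=600, truth_cutoff_hu=150, seed=0)

    def test_amplitude_must_exceed_cutoff(self, clean_phantom):
        with pytest.raises(ValueError, match="exceed"):
            inject_artifacts(clean_phantom, amplitude_hu=100, truth_cutoff_hu=150)

    def test_truth_matches_recomputed_perturbation_field(self, clean_phantom):
        """Ground truth equals an independent per-voxel recomputation of the
        streak equation |A * g(dtheta) / (1 + d/d0)| > cutoff."""
        amplitude, cutoff, decay, n_rays, seed = 600.0, 150.0, 20.0, 24, 3
        out = inject_artifacts(clean_phantom, n_streaks=n_rays,
                               amplitude_hu=amplitude, truth_cutoff_hu=cutoff,
                               decay_mm=decay, seed=seed)
        pert = out.image.data - clean_phantom.image.data

        spec = clean_phantom.spec
        grid = clean_phantom.grid
        rng = np.random.default_rng(seed)
        theta0 = rng.uniform(0, 2 * np.pi / n_rays)
        w = 0.2 * (2 * np.pi / n_rays)
        zs, ys, xs = grid.coordinates_mm()
        cy = spec.air_margin_mm + spec.bath_height_mm / 2
        cx = spec.air_margin_mm + spec.bath_width_mm / 2
        # spot-check a band of voxels in one mid-stem slice
        iz = 10
        expected = np.zeros(grid.shape[1:], dtype=np.float64)
        for iy in range(grid.shape[1]):
            for ix in range(grid.shape[2]):
                dy, dx = ys[iy] - cy, xs[ix] - cx
                r = np.hypot(dx, dy)
                if r > 4 * decay:
                    continue
                theta = np.arctan2(dy, dx)
                step = 2 * np.pi / n_rays
                k = round((theta - theta0) / step)
                dtheta = theta - (theta0 + k * step)
                sign = 1.0 if k % 2 == 0 else -1.0
                expected[iy, ix] = (sign * amplitude
                                    * np.exp(-abs(dtheta / w) ** 6)
                                    / (1 + r / decay))
        applicable = (clean_phantom.labels[iz] != METAL)
        applicable &= clean_phantom.labels[iz] != 0
        fx = spec.stem_proximal_axes_mm[0] / 2
        fy = spec.stem_proximal_axes_mm[1] / 2
        for iy in range(grid.shape[1]):
            for ix in range(grid.shape[2]):
                if ((xs[ix] - cx) / fx) ** 2 + ((ys[iy] - cy) / fy) ** 2 <= 1:
                    applicable[iy, ix] = False
        expected = np.where(applicable, expected, 0.0)
        np.testing.assert_allclose(pert[iz], expected, atol=0.05)
        np.testing.assert_array_equal(out.artifact_truth.data[iz],
                                      np.abs(expected) > cutoff)

    def test_slice_truth_fraction_non_increasing_from_tip(self, clean_phantom):
        out = inject_artifacts(clean_phantom, amplitude_hu=600,
                               truth_cutoff_hu=150, decay_mm=20, seed=5)
        profile = slice_truth_profile(out)
        fractions = [f for _, f in profile]
        assert all(b <= a + 1e-12 for a, b in zip(fractions, fractions[1:]))
        assert fractions[0] > 0

    def test_calibration_hits_target_fraction(self, clean_phantom):
        voi = voi_mask(clean_phantom, "bone_marrow")
        from maraq.phantom import SMOOTHING_TWIST_RAD_PER_MM
        w = calibrate_truth_fraction(
            clean_phantom, voi, 15.0, amplitude_hu=600.0, decay_mm=50.0,
            truth_cutoff_hu=150.0, seed=2,
            twist_rad_per_mm=SMOOTHING_TWIST_RAD_PER_MM)
        out = inject_artifacts(
            clean_phantom, amplitude_hu=600.0, decay_mm=50.0,
            truth_cutoff_hu=150.0, seed=2, ray_width_rad=w,
            twist_rad_per_mm=SMOOTHING_TWIST_RAD_PER_MM)
        got = 100 * (out.artifact_truth.data & voi.data).sum() / voi.n_voxels
        assert got == pytest.approx(15.0, abs=0.3)


class TestAddNoise:
    def test_sigma_zero_identity_and_negative_rejected(self, clean_phantom):
        out = add_noise(clean_phantom, 0.0, seed=1)
        np.testing.assert_array_equal(out.image.data, clean_phantom.image.data)
        with pytest.raises(ValueError):
            add_noise(clean_phantom, -1.0)

    def test_same_seed_identical(self, clean_phantom):
        a = add_noise(clean_phantom, 34.62, seed=9)
        b = add_noise(clean_phantom, 34.62, seed=9)
        np.testing.assert_array_equal(a.image.data, b.image.data)

    def test_water_sd_calibrated_within_2_percent(self, coarse_spec, eid140):
        """Sample SD over a large water region recovers the configured sigma
        (34.62 HU, conventional 140 kVp)."""
        bath = build_water_bath(coarse_spec, eid140)
        noisy = add_noise(bath, 34.62, seed=4)
        water = noisy.image.data[noisy.labels == WATER]
        assert water.size > 1e5
        sd = water.std(ddof=1)
        assert abs(sd - 34.62) / 34.62 < 0.02

    def test_labels_and_truth_untouched(self, clean_phantom):
        streaked = inject_artifacts(clean_phantom, amplitude_hu=600,
                                    truth_cutoff_hu=150, seed=1)
        noisy = add_noise(streaked, 50.0, seed=2)
        np.testing.assert_array_equal(noisy.labels, streaked.labels)
        np.testing.assert_array_equal(noisy.artifact_truth.data,
                                      streaked.artifact_truth.data)


class TestDetectorNoise:
    def test_single_subpixel_gives_unit_sd(self):
        assert simulate_detector_noise(1, 100_000, seed=0) == pytest.approx(1.0, rel=0.02)

    def test_sixteen_subpixels_give_quarter_sd(self):
        assert simulate_detector_noise(16, 100_000, seed=0) == pytest.approx(0.25, rel=0.02)

    def test_half_subpixels_raise_noise_by_sqrt2(self):
        sd8 = simulate_detector_noise(8, 150_000, seed=1)
        sd16 = simulate_detector_noise(16, 150_000, seed=2)
        assert round(sd8 / sd16, 1) == 1.4

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate_detector_noise(0, 10_000)
        with pytest.raises(ValueError):
            simulate_detector_noise(4, 10)


class TestAcquisitionSet:
    def test_pair_on_identical_grids(self, coarse_spec, macro140):
        sims = simulate_acquisition_set(coarse_spec, [macro140], seed=3)
        pair = sims["Macro-HTI 140/75"]
        assert pair.phantom.grid == pair.water_only.grid

    def test_bitwise_deterministic(self, coarse_spec, macro140, eid140):
        kw = dict(spec=coarse_spec, protocols=[eid140, macro140],
                  artifact_params={"amplitude_hu": 600.0, "truth_cutoff_hu": 150.0},
                  seed=17)
        a = simulate_acquisition_set(**kw)
        b = simulate_acquisition_set(**kw)
        for sid in a:
            np.testing.assert_array_equal(a[sid].phantom.image.data,
                                          b[sid].phantom.image.data)
            np.testing.assert_array_equal(a[sid].water_only.image.data,
                                          b[sid].water_only.image.data)

    def test_chess_sigma_defaults_to_sqrt2_times_macro(self, coarse_spec, macro140):
        """A Chess protocol without its own water SD inherits sqrt(2) x the
        Macro sigma: 55.23 -> 78.10 for the water-only series."""
        chess = AcquisitionProtocol.from_table(
            "Chess-HTI 140/75",
            material_sds_hu={"cortical_bone": 123.64, "bone_marrow": 119.87,
                             "water": None},
            water_only_sd_hu=None,
        )
        sims = simulate_acquisition_set(coarse_spec, [macro140, chess], seed=5)
        bath = sims["Chess-HTI 140/75"].water_only
        sd = bath.image.data[bath.labels == WATER].std(ddof=1)
        assert sd == pytest.approx(78.10, rel=0.02)

    def test_shared_streak_geometry_across_series(self, coarse_spec, macro140, eid140):
        sims = simulate_acquisition_set(
            coarse_spec, [eid140, macro140],
            artifact_params={"amplitude_hu": 600.0, "truth_cutoff_hu": 150.0},
            seed=11)
        np.testing.assert_array_equal(
            sims["EID-CT 140"].phantom.artifact_truth.data,
            sims["Macro-HTI 140/75"].phantom.artifact_truth.data)

    def test_requires_a_protocol(self, coarse_spec):
        with pytest.raises(ValueError):
            simulate_acquisition_set(coarse_spec, [], seed=0)
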