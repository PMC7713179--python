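"""Reference statistics, thresholds, classification, erosion, propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maraq.grids import GridMismatchError, RegionMask, VoxelVolume
from maraq.segmentation import (MaterialStats, ThresholdPair,
                                classify_out_of_range, compute_thresholds,
                                erode_mask_mm, propagate_voi, region_stats,
                                segment_artifacts)


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelVolume.from_array(np.asarray(data, dtype=np.float64), spacing)


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return RegionMask.from_array(np.asarray(data, dtype=bool), spacing)


class TestRegionStats:
    def test_constant_region(self):
        vol = _vol(np.full((1, 2, 5), 5.0))
        st_ = region_stats(vol, _mask(np.ones((1, 2, 5))))
        assert (st_.mean_hu, st_.sd_hu, st_.n_voxels) == (5.0, 0.0, 10)

    def test_two_voxels_closed_form(self):
        vol = _vol([[[0.0, 2.0]]])
        st_ = region_stats(vol, _mask([[[1, 1]]]))
        assert st_.mean_hu == pytest.approx(1.0)
        assert st_.sd_hu == pytest.approx(np.sqrt(2.0), abs=1e-4)  # 1.4142

    def test_large_gaussian_region_within_2_percent(self, rng):
        # water-bath statistics of a conventional 140 kVp scan
        mu, sigma = -0.27, 32.95
        data = rng.normal(mu, sigma, size=(60, 60, 60))
        st_ = region_stats(_vol(data), _mask(np.ones((60, 60, 60))))
        assert st_.mean_hu == pytest.approx(mu, abs=0.05 * sigma)
        assert st_.sd_hu == pytest.approx(sigma, rel=0.02)

    def test_empty_and_mismatched_masks_rejected(self):
        vol = _vol(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            region_stats(vol, _mask(np.zeros((2, 2, 2))))
        with pytest.raises(GridMismatchError):
            region_stats(vol, _mask(np.ones((2, 2, 2)), spacing=(2.0, 1.0, 1.0)))


class TestComputeThresholds:
    def test_symmetric_bounds(self):
        thr = compute_thresholds(MaterialStats("w", 0.0, 10.0, 100), k_sd=3)
        assert (thr.lower_hu, thr.upper_hu) == (-30.0, 30.0)

    @pytest.mark.parametrize("mean,sd,expected", [
        (679.70, 80.93, (436.91, 922.49)),   # cortical bone, 140 kVp EID
        (-674.12, 81.22, (-917.78, -430.46)),  # bone marrow, 140 kVp EID
    ])
    def test_published_reference_stats_give_expected_bounds(self, mean, sd, expected):
        thr = compute_thresholds(MaterialStats("m", mean, sd, 1000), k_sd=3)
        assert thr.lower_hu == pytest.approx(expected[0], abs=0.005)
        assert thr.upper_hu == pytest.approx(expected[1], abs=0.005)

    def test_k_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            compute_thresholds(MaterialStats("m", 0, 1, 10), k_sd=0)


class TestClassifyOutOfRange:
    THR = ThresholdPair("cortical_bone", 436.91, 922.49)

    def test_example_values(self):
        vol = _vol([[[400.0, 500.0, 1000.0]]])
        np.testing.assert_array_equal(
            classify_out_of_range(vol, self.THR).data, [[[True, False, True]]])

    def test_value_on_bound_is_normal(self):
        vol = _vol([[[436.91, 922.49]]])
        assert classify_out_of_range(vol, self.THR).n_voxels == 0

    def test_matches_per_voxel_brute_force(self, rng):
        data = rng.uniform(-1200, 1200, size=(8, 9, 10))
        got = classify_out_of_range(_vol(data), self.THR).data
        for idx in np.ndindex(data.shape):
            v = data[idx]
            assert got[idx] == (v < 436.91 or v > 922.49)


class TestErodeMask:
    def test_margin_zero_is_identity(self, rng):
        mask = _mask(rng.random((5, 6, 7)) > 0.5)
        np.testing.assert_array_equal(erode_mask_mm(mask, 0.0).data, mask.data)

    def test_cube_shrinks_by_margin(self):
        cube = np.zeros((14, 14, 14), bool)
        cube[2:12, 2:12, 2:12] = True  # 10 mm cube at 1 mm spacing
        eroded = erode_mask_mm(_mask(cube), 2.0)
        assert eroded.n_voxels == 6 ** 3
        assert eroded.data[4:10, 4:10, 4:10].all()

    def test_matches_brute_force_distance(self, rng):
        spacing = (2.0, 1.0, 1.0)
        mask = np.zeros((6, 8, 8), bool)
        mask[1:5, 2:7, 1:6] = True
        margin = 1.5
        eroded = erode_mask_mm(_mask(mask, spacing), margin).data
        comp = np.argwhere(~mask) * np.array(spacing)
        for idx in np.argwhere(mask):
            d = np.sqrt((((idx * np.array(spacing)) - comp) ** 2).sum(axis=1)).min()
            assert eroded[tuple(idx)] == (d > margin)

    def test_oversized_margin_empties_mask(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert erode_mask_mm(_mask(mask), 10.0).n_voxels == 0


class TestPropagateVoi:
    def test_same_grid_copies_mask(self, rng):
        voi = _mask(rng.random((4, 5, 6)) > 0.5)
        target = _vol(np.zeros((4, 5, 6)))
        np.testing.assert_array_equal(propagate_voi(voi, target).data, voi.data)

    def test_different_slice_count_rejected(self):
        with pytest.raises(GridMismatchError):
            propagate_voi(_mask(np.ones((4, 5, 6))), _vol(np.zeros((5, 5, 6))))

    def test_different_spacing_rejected(self):
        with pytest.raises(GridMismatchError):
            propagate_voi(_mask(np.ones((4, 5, 6))),
                          _vol(np.zeros((4, 5, 6)), spacing=(2.0, 1.0, 1.0)))


class TestSegmentArtifacts:
    def test_all_in_range_gives_empty_mask(self):
        vol = _vol(np.full((3, 3, 3), 500.0))
        thr = ThresholdPair("m", 436.91, 922.49)
        voi = _mask(np.ones((3, 3, 3)))
        assert segment_artifacts(vol, thr, voi).n_voxels == 0

    def test_artifacts_outside_voi_excluded(self):
        data = np.full((2, 2, 2), 1000.0)
        thr = ThresholdPair("m", -100.0, 100.0)
        voi = np.zeros((2, 2, 2), bool)
        voi[0] = True
        seg = segment_artifacts(_vol(data), thr, _mask(voi))
        assert seg.data[0].all() and not seg.data[1].any()

    def test_strong_streaks_recovered_within_voi(self, clean_phantom):
        """With streak amplitude 10x the noise SD, the segmented set contains
        truth ∩ VOI and stays inside the VOI."""
        from maraq.phantom import add_noise, inject_artifacts, reference_mask, voi_mask
        sigma = 30.0
        streaked = inject_artifacts(clean_phantom, amplitude_hu=10 * sigma,
                                    truth_cutoff_hu=3 * sigma, decay_mm=50,
                                    support_mm=90, seed=13)
        noisy = add_noise(streaked, sigma, seed=14)
        ref = reference_mask(noisy, "bone_marrow", margin_mm=2.0)
        thr = compute_thresholds(region_stats(noisy.image, ref), k_sd=3)
        voi = voi_mask(noisy, "bone_marrow")
        seg = segment_artifacts(noisy.image, thr, voi)
        assert not (seg.data & ~voi.data).any()
        # voxels perturbed beyond threshold + 3*noise cannot be pushed back
        # in range by noise except with ~Phi(-3) probability
        pert = np.abs(streaked.image.data - clean_phantom.image.data)
        strong = (pert > 6 * sigma) & voi.data
        assert strong.sum() > 1000
        miss = (strong & ~seg.data).sum() / strong.sum()
        assert miss < 0.005


class TestInvariants:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.5, 5.0), st.floats(0.1, 2.0), st.integers(0, 2 ** 31 - 1))
    def test_growing_k_never_grows_artifact_mask(self, k, dk, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 50, size=(4, 8, 8))
        stats = MaterialStats("m", 0.0, 50.0, 100)
        small = classify_out_of_range(_vol(data), compute_thresholds(stats, k))
        large = classify_out_of_range(_vol(data), compute_thresholds(stats, k + dk))
        assert not (large.data & ~small.data).any()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-500, 500), st.integers(0, 2 ** 31 - 1))
    def test_shift_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 50, size=(4, 8, 8))
        thr = ThresholdPair("m", -90.0, 110.0)
        shifted_thr = ThresholdPair("m", -90.0 + c, 110.0 + c)
        a = classify_out_of_range(_vol(data), thr).data
        b = classify_out_of_range(_vol(data + c), shifted_thr).data
        np.testing.assert_array_equal(a, b)

    def test_gaussian_calibration_at_k3(self, rng):
        """Out-of-range fraction of an artifact-free Gaussian region at k=3
        sits within 3 Monte-Carlo SEs of 2*Phi(-3) = 0.27%."""
        n = 500_000
        p = 2 * 0.0013498980316300945
        data = rng.normal(100.0, 20.0, size=n).reshape(50, 100, 100)
        thr = compute_thresholds(MaterialStats("m", 100.0, 20.0, n), k_sd=3)
        frac = classify_out_of_range(_vol(data), thr).n_voxels / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se
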