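"""Skeletonization, exact EDT and centerline diameter estimation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from ecmarch import fiber_architecture as fa
from ecmarch import synthetic_data as sd
from ecmarch.segmentation import BinaryMask

from conftest import make_single_fiber, plus_mask


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each fiber pixel to any non-fiber
    pixel, by exhaustive search."""
    out = np.zeros(mask.shape, dtype=float)
    background = np.argwhere(~mask)
    for r, c in np.argwhere(mask):
        d2 = ((background - (r, c)) ** 2).sum(axis=1)
        out[r, c] = np.sqrt(d2.min())
    return out


class TestSkeletonize:
    def test_horizontal_bar_gives_single_centerline(self):
        m = np.zeros((20, 50), dtype=bool)
        m[8:13, :] = True
        skel = fa.skeletonize(BinaryMask(m))
        rows = skel.coords[:, 0]
        # 1-px line at mid-height (thinning may bend by 1 px at bar ends)
        assert np.median(rows) == 10
        assert np.abs(rows - 10).max() <= 1
        per_col = skel.pixels.sum(axis=0)
        assert per_col.max() <= 2
        assert len(skel.branch_points) == 0

    def test_plus_shape_has_one_branch_cluster(self):
        skel = fa.skeletonize(plus_mask())
        assert len(skel.branch_points) >= 1
        bp = np.zeros(skel.pixels.shape, dtype=bool)
        bp[tuple(skel.branch_points.T)] = True
        n_clusters = ndi.label(bp, structure=np.ones((3, 3)))[1]
        assert n_clusters == 1

    def test_isolated_pixel_survives_when_size_floor_disabled(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 4] = True
        skel = fa.skeletonize(BinaryMask(m), min_component_px=1)
        assert skel.pixels[4, 4] and skel.pixels.sum() == 1

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            skel = fa.skeletonize(BinaryMask(np.zeros((10, 10), dtype=bool)))
        assert not skel.pixels.any()

    def test_skeleton_subset_of_mask_and_topology(self, fiber_scene):
        _, truth = fiber_scene
        skel = fa.skeletonize(truth.true_mask)
        assert not (skel.pixels & ~truth.true_mask.pixels).any()
        n_mask = ndi.label(truth.true_mask.pixels, np.ones((3, 3)))[1]
        n_skel = ndi.label(skel.pixels, np.ones((3, 3)))[1]
        assert n_skel == n_mask


class TestDistanceTransform:
    def test_single_background_pixel(self):
        m = np.ones((10, 10), dtype=bool)
        m[0, 0] = False
        dmap = fa.distance_transform(BinaryMask(m))
        assert dmap.values[0, 3] == pytest.approx(3.0)
        assert dmap.values[0, 0] == 0.0

    def test_bar_centerline_distance(self):
        m = np.zeros((20, 20), dtype=bool)
        m[8:13, :] = True
        dmap = fa.distance_transform(BinaryMask(m))
        assert dmap.values[10, 10] == pytest.approx(3.0)

    def test_zero_on_non_fiber(self, fiber_scene):
        _, truth = fiber_scene
        dmap = fa.distance_transform(truth.true_mask)
        assert (dmap.values[~truth.true_mask.pixels] == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(5, 41, size=2)
        mask = rng.uniform(size=shape) < 0.6
        if mask.all():
            mask[0, 0] = False
        dmap = fa.distance_transform(BinaryMask(mask))
        np.testing.assert_allclose(dmap.values, brute_force_edt(mask))


class TestDiameterEstimation:
    @pytest.mark.parametrize("width", [3, 5, 9])
    def test_isolated_bar_recovery(self, width):
        _, truth = make_single_fiber(width)
        dist = fa.estimate_fiber_diameters(truth.true_mask)
        assert dist.mean == pytest.approx(width, abs=1.0)

    def test_recovery_monotone_in_width(self):
        means = []
        for width in (3, 5, 9):
            _, truth = make_single_fiber(width)
            means.append(fa.estimate_fiber_diameters(truth.true_mask).mean)
        assert means[0] < means[1] < means[2]

    def test_crossing_bars_corrected(self):
        mask = plus_mask()
        skel = fa.skeletonize(mask)
        corrected = fa.estimate_fiber_diameters(mask, skel)
        uncorrected = fa.estimate_fiber_diameters(mask, skel, intersection_correction=False)
        assert corrected.mean == pytest.approx(5, abs=1.0)
        assert corrected.n < uncorrected.n

    def test_correction_restores_crossing_free_reading(self):
        # on crossing scenes the corrected estimate must sit at least as
        # close to the estimator's crossing-free reading of the same
        # fibers as the uncorrected one
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, shape = 8, (128, 128)
            centers = np.column_stack(
                [rng.integers(0, 128, n), rng.integers(0, 128, n)]
            ).astype(float)
            angles = rng.uniform(-90, 90, n)
            widths = np.full(n, 5.0)
            union = BinaryMask(sd.render_fiber_mask(shape, centers, angles, widths))
            corrected = fa.estimate_fiber_diameters(union)
            uncorrected = fa.estimate_fiber_diameters(union, intersection_correction=False)
            solo = np.concatenate(
                [
                    fa.estimate_fiber_diameters(
                        BinaryMask(
                            sd.render_fiber_mask(
                                shape, centers[i : i + 1], angles[i : i + 1], widths[i : i + 1]
                            )
                        )
                    ).diameters_px
                    for i in range(n)
                ]
            )
            reference = solo.mean()
            assert abs(corrected.mean - reference) <= abs(uncorrected.mean - reference) + 1e-9

    def test_nm_calibration(self):
        _, truth = make_single_fiber(5)
        mask = BinaryMask(truth.true_mask.pixels, pixel_size=20.0)
        dist = fa.estimate_fiber_diameters(mask)
        np.testing.assert_allclose(dist.diameters_nm, dist.diameters_px * 20.0)


class TestFiberSummary:
    def test_constant_diameters(self):
        dist = fa.FiberDiameterDistribution(
            np.array([5.0, 5.0, 5.0]), np.zeros((3, 2), dtype=int)
        )
        out = fa.fiber_summary(dist, bin_width=1.0)
        assert (out["counts"] > 0).sum() == 1
        assert out["mean_px"] == 5.0
        assert out["sd_px"] == 0.0

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1, 10, size=200)
        dist = fa.FiberDiameterDistribution(d, np.zeros((200, 2), dtype=int))
        out = fa.fiber_summary(dist, bin_width=0.7)
        assert out["counts"].sum() == 200

    def test_simple_mean(self):
        dist = fa.FiberDiameterDistribution(
            np.array([3.0, 5.0, 7.0]), np.zeros((3, 2), dtype=int)
        )
        assert fa.fiber_summary(dist)["mean_px"] == 5.0

    def test_bad_bin_width(self):
        dist = fa.FiberDiameterDistribution(np.array([3.0]), np.zeros((1, 2), dtype=int))
        with pytest.raises(ValueError, match="bin_width"):
            fa.fiber_summary(dist, bin_width=0)
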