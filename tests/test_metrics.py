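"""Evaluation metrics against brute-force oracles and analytic cases.

The oracles are deliberately naive O(|A|*|B|) double loops over voxel pairs
and pure-python set algebra; the implementation must match them exactly.
"""

import numpy as np
import pytest

from hipseg import metrics
from hipseg.ct_io import LabelVolume
from hipseg.metrics import VoxelSet
from conftest import random_blob_mask


def brute_doc(a, b):
    sa, sb = set(map(tuple, a)), set(map(tuple, b))
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def brute_directed_hd(a, b, spacing):
    s = np.asarray(spacing)
    return max(
        min(np.sqrt((((np.asarray(x) - np.asarray(y)) * s) ** 2).sum()) for y in b)
        for x in a
    )


def brute_msd(a, b, spacing):
    s = np.asarray(spacing)

    def nearest(x, pts):
        return min(np.sqrt((((np.asarray(x) - np.asarray(p)) * s) ** 2).sum()) for p in pts)

    total = sum(nearest(x, b) for x in a) + sum(nearest(y, a) for y in b)
    return total / (len(a) + len(b))


class TestDoc:
    def test_identical_sets_give_one(self):
        a = VoxelSet(np.array([[0, 0, 0], [1, 1, 1]]), (1, 1, 1))
        assert metrics.doc(a, a) == 1.0

    def test_disjoint_sets_give_zero(self):
        a = VoxelSet(np.array([[0, 0, 0]]), (1, 1, 1))
        b = VoxelSet(np.array([[5, 5, 5]]), (1, 1, 1))
        assert metrics.doc(a, b) == 0.0

    def test_partial_overlap_exact_fraction(self):
        # |AS|=2, |GT|=4, overlap 2 -> 2*2/(2+4) = 2/3
        a = VoxelSet(np.array([[0, 0, 0], [0, 0, 1]]), (1, 1, 1))
        b = VoxelSet(
            np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0], [1, 0, 0]]), (1, 1, 1)
        )
        assert metrics.doc(a, b) == pytest.approx(2.0 / 3.0)

    def test_both_empty_rejected(self):
        e = VoxelSet(np.empty((0, 3)), (1, 1, 1))
        with pytest.raises(metrics.EmptySetError):
            metrics.doc(e, e)


class TestPointToSet:
    def test_member_point_distance_zero(self):
        a = VoxelSet(np.array([[2, 3, 4]]), (1, 1, 1))
        assert metrics.point_to_set_distance((2, 3, 4), a) == 0.0

    def test_pythagorean_distance(self):
        a = VoxelSet(np.array([[3, 4, 0]]), (1, 1, 1))
        assert metrics.point_to_set_distance((0, 0, 0), a) == pytest.approx(5.0)

    def test_distance_linear_in_spacing(self):
        a1 = VoxelSet(np.array([[3, 4, 0]]), (1, 1, 1))
        a2 = VoxelSet(np.array([[3, 4, 0]]), (2, 2, 2))
        assert metrics.point_to_set_distance((0, 0, 0), a2) == pytest.approx(
            2 * metrics.point_to_set_distance((0, 0, 0), a1)
        )


class TestHausdorff:
    def test_two_point_example_both_directions(self):
        a = VoxelSet(np.array([[0, 0]]), (1, 1))
        b = VoxelSet(np.array([[3, 4]]), (1, 1))
        assert metrics.directed_hausdorff(a, b) == pytest.approx(5.0)
        assert metrics.directed_hausdorff(b, a) == pytest.approx(5.0)
        assert metrics.hausdorff(a, b) == pytest.approx(5.0)

    def test_subset_has_zero_directed_distance(self):
        b = VoxelSet(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]]), (1, 1, 1))
        a = VoxelSet(np.array([[1, 0, 0]]), (1, 1, 1))
        assert metrics.directed_hausdorff(a, b) == 0.0

    def test_unit_separated_parallel_segments(self):
        a = VoxelSet(np.array([[i, 0] for i in range(5)]), (1, 1))
        b = VoxelSet(np.array([[i, 1] for i in range(5)]), (1, 1))
        assert metrics.hausdorff(a, b) == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        a = VoxelSet(np.array([[0, 0, 0]]), (1, 1, 1))
        with pytest.raises(metrics.EmptySetError):
            metrics.directed_hausdorff(a, VoxelSet(np.empty((0, 3)), (1, 1, 1)))


class TestMeanSurfaceDistance:
    def test_identical_surfaces_give_zero(self):
        a = VoxelSet(np.array([[0, 0, 0], [3, 3, 3]]), (1, 1, 1))
        assert metrics.mean_surface_distance(a, a) == 0.0

    def test_two_points_five_mm_apart(self):
        a = VoxelSet(np.array([[0, 0, 0]]), (1, 1, 1))
        b = VoxelSet(np.array([[0, 3, 4]]), (1, 1, 1))
        assert metrics.mean_surface_distance(a, b) == pytest.approx(5.0)


class TestExtractSurface:
    def test_solid_3cube_has_26_surface_voxels(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        assert len(metrics.extract_surface(mask, spacing=(1, 1, 1))) == 26

    def test_single_voxel_is_its_own_surface(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        surf = metrics.extract_surface(mask, spacing=(1, 1, 1))
        assert np.array_equal(surf.coordinates, [[1, 1, 1]])

    def test_5cube_surface_excludes_27_interior_voxels(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True
        assert len(metrics.extract_surface(mask, spacing=(1, 1, 1))) == 5**3 - 3**3

    def test_border_touching_mask_counts_as_surface(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        assert len(metrics.extract_surface(mask, spacing=(1, 1, 1))) == 8

    def test_absent_class_rejected(self):
        lab = LabelVolume(np.zeros((4, 4, 4), dtype=int), (1, 1, 1))
        with pytest.raises(metrics.EmptySetError):
            metrics.extract_surface(lab, cls=1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(20))
    def test_metrics_match_brute_force_on_random_masks(self, trial):
        rng = np.random.default_rng(trial)
        shape = tuple(rng.integers(4, 9, size=3))
        spacing = tuple(rng.uniform(0.5, 3.0, size=3))
        a = np.argwhere(random_blob_mask(rng, shape))
        b = np.argwhere(random_blob_mask(rng, shape))
        if len(a) == 0 or len(b) == 0:
            pytest.skip("degenerate draw")
        va, vb = VoxelSet(a, spacing), VoxelSet(b, spacing)
        assert metrics.doc(va, vb) == pytest.approx(brute_doc(a, b), abs=1e-12)
        assert metrics.directed_hausdorff(va, vb) == pytest.approx(
            brute_directed_hd(a, b, spacing), abs=1e-9
        )
        assert metrics.hausdorff(va, vb) == pytest.approx(
            max(brute_directed_hd(a, b, spacing), brute_directed_hd(b, a, spacing)),
            abs=1e-9,
        )
        assert metrics.mean_surface_distance(va, vb) == pytest.approx(
            brute_msd(a, b, spacing), abs=1e-9
        )

    def test_hausdorff_symmetric_and_bounds_msd(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            a = np.argwhere(random_blob_mask(rng, (6, 6, 6)))
            b = np.argwhere(random_blob_mask(rng, (6, 6, 6)))
            if len(a) == 0 or len(b) == 0:
                continue
            va, vb = VoxelSet(a, (1, 1, 1)), VoxelSet(b, (1, 1, 1))
            hd = metrics.hausdorff(va, vb)
            assert hd == metrics.hausdorff(vb, va)
            assert hd >= metrics.mean_surface_distance(va, vb) >= 0


class TestEvaluateCase:
    def _vol(self, mask, spacing=(1, 1, 1)):
        return LabelVolume(mask.astype(np.int16), spacing)

    def test_perfect_prediction(self):
        mask = np.zeros((8, 8, 8), dtype=int)
        mask[2:6, 2:6, 2:6] = 1
        rep = metrics.evaluate_case(self._vol(mask), self._vol(mask))
        assert rep[1].doc == 1.0
        assert rep[1].hd_mm == 0.0
        assert rep[1].msd_mm == 0.0

    def test_one_voxel_dilation_has_unit_hausdorff(self):
        from scipy import ndimage

        gt = np.zeros((10, 10, 10), dtype=int)
        gt[3:7, 3:7, 3:7] = 1
        pred = ndimage.binary_dilation(
            gt.astype(bool), ndimage.generate_binary_structure(3, 1)
        ).astype(int)
        rep = metrics.evaluate_case(self._vol(pred), self._vol(gt))
        assert rep[1].hd_mm == pytest.approx(1.0)

    def test_empty_prediction_flagged_undefined(self):
        gt = np.zeros((6, 6, 6), dtype=int)
        gt[2:4, 2:4, 2:4] = 1
        rep = metrics.evaluate_case(self._vol(np.zeros_like(gt)), self._vol(gt))
        assert rep[1].doc == 0.0
        assert rep[1].hd_mm is None and rep[1].msd_mm is None

    def test_shape_mismatch_rejected(self):
        a = self._vol(np.zeros((4, 4, 4), dtype=int))
        b = self._vol(np.zeros((4, 4, 5), dtype=int))
        with pytest.raises(ValueError):
            metrics.evaluate_case(a, b)

    def test_distances_scale_with_spacing(self):
        gt = np.zeros((8, 8, 8), dtype=int)
        gt[2:5, 2:5, 2:5] = 1
        pred = np.zeros_like(gt)
        pred[3:6, 3:6, 3:6] = 1
        r1 = metrics.evaluate_case(self._vol(pred), self._vol(gt))
        r2 = metrics.evaluate_case(
            self._vol(pred, (2, 2, 2)), self._vol(gt, (2, 2, 2))
        )
        assert r2[1].hd_mm == pytest.approx(2 * r1[1].hd_mm)
        assert r2[1].msd_mm == pytest.approx(2 * r1[1].msd_mm)
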