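"""Overlap metric, Hausdorff distance, centerline extraction and diameter
estimation, each against brute-force or analytic oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from coroseg import (BinaryMask, Centerline, extract_centerline, hausdorff,
                     measure_diameters, overlap_metric, overlap_metric_2d)
from coroseg.evaluation import boundary_voxels


def random_mask(rng, shape=(10, 10, 10), p=0.1):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return BinaryMask(m)


class TestOverlapMetric:
    def test_closed_forms(self, rng):
        a = random_mask(rng)
        assert overlap_metric(a, a) == 1.0
        b = BinaryMask(~a.values & (rng.random(a.shape) < 0.1))
        if b.count():
            assert overlap_metric(a, b) == 0.0
        # |a|=|b|=10, |a∩b|=8 -> 0.8
        x = np.zeros((5, 5, 5), dtype=bool)
        y = np.zeros((5, 5, 5), dtype=bool)
        x.flat[:10] = True
        y.flat[2:12] = True
        assert overlap_metric(BinaryMask(x), BinaryMask(y)) == pytest.approx(0.8)
        assert overlap_metric(BinaryMask(np.zeros((3, 3, 3), bool)),
                              BinaryMask(np.zeros((3, 3, 3), bool))) == 1.0

    @given(seed=st.integers(0, 50))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask(rng), random_mask(rng)
        om = overlap_metric(a, b)
        assert om == overlap_metric(b, a)
        assert 0.0 <= om <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            overlap_metric(BinaryMask(np.zeros((3, 3, 3), bool)),
                           BinaryMask(np.zeros((4, 3, 3), bool)))

    def test_2d_averages_over_reference_slices(self):
        t = np.zeros((6, 6, 4), dtype=bool)
        p = np.zeros((6, 6, 4), dtype=bool)
        t[2:4, 2:4, 1] = True          # slice 1: pred matches fully
        p[2:4, 2:4, 1] = True
        t[2:4, 2:4, 2] = True          # slice 2: pred misses entirely
        p[0:2, 0:2, 3] = True          # slice 3: truth empty -> skipped
        assert overlap_metric_2d(BinaryMask(p), BinaryMask(t)) == pytest.approx(0.5)


class TestHausdorff:
    def test_identity_and_two_points(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        a = BinaryMask(m)
        assert hausdorff(a, a) == 0.0
        x = np.zeros((6, 6, 6), dtype=bool)
        y = np.zeros((6, 6, 6), dtype=bool)
        x[0, 0, 0] = True
        y[3, 4, 0] = True
        assert hausdorff(BinaryMask(x), BinaryMask(y)) == pytest.approx(5.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        a, b = random_mask(rng, p=0.15), random_mask(rng, p=0.15)
        sp = (0.7, 1.0, 1.3)
        got = hausdorff(BinaryMask(a.values, sp), BinaryMask(b.values, sp))
        x = boundary_voxels(a) * np.array(sp)
        y = boundary_voxels(b) * np.array(sp)
        d = cdist(x, y)
        brute = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert got == pytest.approx(brute, abs=1e-12)

    def test_symmetry_and_triangle_inequality(self, rng):
        masks = [random_mask(rng) for _ in range(3)]
        d01 = hausdorff(masks[0], masks[1])
        assert d01 == hausdorff(masks[1], masks[0])
        d02 = hausdorff(masks[0], masks[2])
        d12 = hausdorff(masks[1], masks[2])
        assert d02 <= d01 + d12 + 1e-12

    def test_empty_mask_rejected(self):
        m = BinaryMask(np.zeros((4, 4, 4), dtype=bool))
        n = np.zeros((4, 4, 4), dtype=bool)
        n[1, 1, 1] = True
        with pytest.raises(ValueError):
            hausdorff(m, BinaryMask(n))


class TestCenterline:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        cl = extract_centerline(BinaryMask(m))
        assert len(cl.polylines) == 1
        assert len(cl.polylines[0]) == 1
        assert cl.branch_points == []

    def test_straight_cylinder_axis(self, tube_factory):
        # radius 4, length 60 along z; thinning may erode at most ~one
        # radius from each open end, and the skeleton must lie on the axis
        mask = tube_factory((20, 20, 70), (10, 10, 5), (10, 10, 64), 4.0)
        cl = extract_centerline(mask)
        assert len(cl.polylines) == 1
        pts = cl.polylines[0]
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert 60 - 2 * 4 <= arc <= 60
        assert np.abs(pts[:, :2] - 10).max() <= 1.0
        assert cl.branch_points == []

    def test_y_tube_has_one_branch_point(self, tube_factory):
        a = tube_factory((40, 40, 48), (20, 20, 4), (20, 20, 24), 3.0)
        b = tube_factory((40, 40, 48), (20, 20, 24), (10, 20, 42), 3.0)
        c = tube_factory((40, 40, 48), (20, 20, 24), (30, 20, 42), 3.0)
        mask = BinaryMask(a.values | b.values | c.values)
        cl = extract_centerline(mask)
        assert len(cl.branch_points) == 1
        assert len(cl.polylines) == 3

    def test_skeleton_of_connected_mask_is_connected(self, tube_factory):
        from scipy import ndimage

        mask = tube_factory((30, 20, 40), (5, 10, 5), (24, 10, 34), 3.0)
        cl = extract_centerline(mask)
        skel = np.zeros(mask.shape, dtype=bool)
        for line in cl.polylines:
            skel[line[:, 0], line[:, 1], line[:, 2]] = True
        _, n = ndimage.label(skel, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_centerline(BinaryMask(np.zeros((4, 4, 4), bool)))


class TestDiameters:
    def test_digitized_cylinder_radius_recovered(self, tube_factory):
        sp = 0.625
        r_mm = 2.35
        mask = tube_factory((24, 24, 40), (12, 12, 4), (12, 12, 36), r_mm,
                            spacing=(sp, sp, sp))
        line = Centerline([np.array([[12.0, 12.0, float(k)]
                                     for k in range(8, 32)])])
        pairs = measure_diameters(mask, line, step=2)
        vals = np.array([v for _, v in pairs])
        assert np.mean(vals) == pytest.approx(r_mm, rel=0.05)
        # doubled value with the diameter flag
        pairs_d = measure_diameters(mask, line, step=2,
                                    circle_equivalent_diameter=True)
        np.testing.assert_allclose([v for _, v in pairs_d], 2 * vals, rtol=1e-12)
        # stability along a constant tube: < 3% spread
        assert (vals.max() - vals.min()) / vals.mean() < 0.03

    def test_centerline_outside_mask_rejected(self, tube_factory):
        mask = tube_factory((16, 16, 16), (8, 8, 2), (8, 8, 14), 2.0)
        line = Centerline([np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 2.0]])])
        with pytest.raises(ValueError):
            measure_diameters(mask, line)
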