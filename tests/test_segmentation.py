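import numpy as np
import pytest

from atlasmap import (
    RegionMask,
    containment_fraction,
    cylinder_region,
    density_mask,
    epicenter,
    half_mask,
    level_density,
    mirror_points,
)


def brute_level_density(points, z_level, radius, shape_xy):
    """O(cells × points) reference implementation."""
    nx, ny = shape_xy
    out = np.zeros((nx, ny), dtype=int)
    for i in range(nx):
        for j in range(ny):
            for px, py, pz in points:
                if int(np.floor(pz)) == z_level and (px - i) ** 2 + (py - j) ** 2 <= radius**2:
                    out[i, j] += 1
    return out


class TestMirror:
    def test_point_on_midline_is_fixed(self):
        pts = np.array([[243.6, 1.0, 2.0]])
        out = mirror_points(pts, 243.6)
        assert np.allclose(out, [[243.6, 1, 2], [243.6, 1, 2]])

    def test_published_midline_reflection(self):
        # epicenter 1.78 mm lateral of a 243.6-voxel midline at 39 µm
        out = mirror_points(np.array([[198.0, 0.0, 0.0]]), 243.6)
        assert np.isclose(out[1, 0], 289.2)

    def test_involution(self, rng):
        pts = rng.uniform(0, 100, size=(20, 3))
        once = mirror_points(pts, 50.0)
        twice = mirror_points(once[len(pts):], 50.0)
        assert np.allclose(twice[len(pts):], pts)


class TestLevelDensity:
    def test_empty_level_is_zero(self):
        out = level_density(np.array([[5.0, 5.0, 9.0]]), 2, 3.0, (10, 10))
        assert (out == 0).all()

    def test_three_coincident_points(self):
        pts = np.tile([[7.3, 6.2, 2.5]], (3, 1))
        out = level_density(pts, 2, 3.0, (15, 15))
        oracle = brute_level_density(pts, 2, 3.0, (15, 15))
        assert (out == oracle).all()
        assert out.max() == 3
        assert out[int(7.3), int(6.2)] == 3

    def test_matches_brute_force_on_random_cloud(self, rng):
        pts = rng.uniform(0, 30, size=(200, 3))
        out = level_density(pts, 4, 10.0, (30, 30))
        assert (out == brute_level_density(pts, 4, 10.0, (30, 30))).all()

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            level_density(np.zeros((1, 3)), 0, 0.0, (5, 5))


class TestDensityMask:
    def test_two_points_below_strict_threshold(self):
        pts = np.tile([[5.0, 5.0, 2.0]], (2, 1))
        mask = density_mask(pts, (10, 10, 5), radius=3, threshold=2)
        assert mask.n_voxels == 0

    def test_three_coincident_points_make_a_disc(self):
        pts = np.tile([[10.0, 10.0, 2.0]], (3, 1))
        mask = density_mask(pts, (21, 21, 5), radius=4, threshold=2)
        level = mask.mask[:, :, 2]
        oracle = brute_level_density(pts, 2, 4.0, (21, 21)) > 2
        assert (level == oracle).all()
        assert mask.mask[:, :, :2].sum() == 0 and mask.mask[:, :, 3:].sum() == 0

    def test_empty_points_warn(self):
        with pytest.warns(UserWarning):
            mask = density_mask(np.empty((0, 3)), (5, 5, 5))
        assert mask.n_voxels == 0

    def test_monotone_in_radius_and_threshold(self, rng):
        pts = rng.uniform(0, 20, size=(60, 3))
        base = density_mask(pts, (20, 20, 20), radius=5, threshold=2)
        smaller_r = density_mask(pts, (20, 20, 20), radius=3, threshold=2)
        higher_t = density_mask(pts, (20, 20, 20), radius=5, threshold=4)
        assert not (smaller_r.mask & ~base.mask).any()
        assert not (higher_t.mask & ~base.mask).any()

    def test_mirrored_cloud_gives_symmetric_mask(self, rng):
        pts = rng.normal([10, 15, 8], 2.0, size=(60, 3))
        midline = 16.0  # integer-symmetric grid position: x -> 32 - x
        mask = density_mask(mirror_points(pts, midline), (33, 30, 16), radius=3)
        flipped = mask.mask[::-1, :, :]
        assert (mask.mask == flipped).all()


class TestEpicenter:
    def test_single_voxel(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[5, 6, 7] = True
        assert np.allclose(epicenter(m), (5, 6, 7))

    def test_two_voxel_symmetry(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = m[2, 0, 0] = True
        assert np.allclose(epicenter(m), (1, 0, 0))

    def test_matches_mean_over_coordinates(self, rng):
        m = rng.random((6, 7, 8)) > 0.7
        if not m.any():
            m[0, 0, 0] = True
        oracle = np.array([c.mean() for c in np.nonzero(m)])
        assert np.allclose(epicenter(m), oracle)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            epicenter(np.zeros((3, 3, 3), dtype=bool))


class TestContainment:
    def test_all_inside(self):
        m = np.ones((5, 5, 5), dtype=bool)
        assert containment_fraction(m, np.full((10, 3), 2.5)) == 1.0

    def test_none_inside(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        assert containment_fraction(m, np.full((10, 3), 2.5)) == 0.0

    def test_mixed_matches_per_point_loop(self, rng):
        m = rng.random((6, 6, 6)) > 0.5
        pts = rng.uniform(-1, 7, size=(100, 3))
        hits = 0
        for p in pts:
            i, j, k = (int(np.floor(c)) for c in p)
            if 0 <= i < 6 and 0 <= j < 6 and 0 <= k < 6 and m[i, j, k]:
                hits += 1
        assert containment_fraction(m, pts) == hits / 100

    def test_empty_points_raise(self):
        with pytest.raises(ValueError):
            containment_fraction(np.ones((2, 2, 2), dtype=bool), np.empty((0, 3)))

    def test_nondecreasing_in_density_radius(self, rng):
        pts = rng.normal(10, 3, size=(80, 3))
        fracs = []
        for radius in (2, 4, 6, 8):
            mask = density_mask(pts, (20, 20, 20), radius=radius, threshold=2)
            fracs.append(containment_fraction(mask, pts))
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestCylinder:
    def test_zero_diameter_is_empty(self):
        m = cylinder_region((10, 10, 10), 5.0, (0, 600), (4.0, 4.0), 0.0)
        assert m.n_voxels == 0

    def test_per_level_disc_count_matches_brute_force(self):
        # 500 µm diameter at 39 µm voxels -> in-plane radius 6.41 voxels
        m = cylinder_region((30, 40, 30), 20.0, (0, 600), (15.0, 15.0), 500.0)
        r = 250.0 / 39.0
        brute = sum(
            1
            for i in range(30)
            for k in range(30)
            if (i - 15.0) ** 2 + (k - 15.0) ** 2 <= r * r
        )
        levels = np.flatnonzero(m.mask.any(axis=(0, 2)))
        for j in levels:
            assert m.mask[:, j, :].sum() == brute

    def test_caudal_600um_span_covers_16_levels(self):
        m = cylinder_region((30, 60, 30), 40.0, (0, 600), (15.0, 15.0), 500.0,
                            direction=-1)
        levels = np.flatnonzero(m.mask.any(axis=(0, 2)))
        assert len(levels) == int(np.ceil(600 / 39))  # 16
        assert levels.max() == 40  # the reference level itself is included
        assert levels.min() == 40 - 15

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            cylinder_region((10, 10, 10), 5.0, (600, 0), (4.0, 4.0), 100.0)


def test_half_mask_splits_at_midline():
    m = np.ones((10, 4, 4), dtype=bool)
    left = half_mask(RegionMask(m, "m"), 5.0, "left")
    right = half_mask(RegionMask(m, "m"), 5.0, "right")
    assert left.mask[:5].all() and not left.mask[5:].any()
    assert right.mask[6:].all() and not right.mask[:6].any()
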