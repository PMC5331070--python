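import numpy as np
import pandas as pd
import pytest

from atlasmap import (
    ConfigError,
    GeometryError,
    LabelVolume,
    RegionMask,
    count_by_region,
    edge_lengths,
    edge_summary,
    group_percentages,
    laterality,
    make_label_table,
    mirror_points,
)


def small_volume(rng=None, shape=(8, 8, 8), labels=(1, 2, 3)):
    if rng is None:
        v = np.zeros(shape, dtype=np.int16)
        v[0:4] = 1
        v[4:6] = 2
        v[6:] = 3
    else:
        v = rng.integers(0, max(labels) + 1, size=shape).astype(np.int16)
    table = make_label_table(
        [(1, "r1", "brainstem"), (2, "r2", "midbrain"), (3, "r3", "forebrain")]
    )
    return LabelVolume(v, table)


def table_for(xyz, animals=None):
    xyz = np.asarray(xyz, dtype=float)
    return pd.DataFrame(
        {
            "animal_id": animals if animals is not None else ["A1"] * len(xyz),
            "class": "input",
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )


class TestCountByRegion:
    def test_no_points_gives_zero_table(self):
        vol = small_volume()
        out = count_by_region(table_for(np.empty((0, 3))), vol)
        assert (out["n_pooled"] == 0).all()

    def test_single_point_in_labelled_voxel(self):
        vol = small_volume()
        out = count_by_region(table_for([[4.5, 0.5, 0.5]]), vol)  # label 2
        assert out.set_index("region").loc["r2", "n_pooled"] == 1
        assert out.loc[out.region != "r2", "n_pooled"].sum() == 0

    def test_matches_per_point_loop_oracle(self, rng):
        vol = small_volume(rng)
        xyz = rng.uniform(-1, 9, size=(500, 3))
        animals = rng.choice(["A1", "A2"], size=500)
        out = count_by_region(table_for(xyz, animals), vol).set_index("region")
        tallies = {"r1": 0, "r2": 0, "r3": 0, "unassigned": 0}
        for p in xyz:
            i, j, k = (int(np.floor(c)) for c in p)
            if 0 <= i < 8 and 0 <= j < 8 and 0 <= k < 8 and vol.voxels[i, j, k] > 0:
                tallies[f"r{vol.voxels[i, j, k]}"] += 1
            else:
                tallies["unassigned"] += 1
        for region, n in tallies.items():
            assert out.loc[region, "n_pooled"] == n

    def test_conservation_per_animal_and_pooled(self, rng):
        vol = small_volume(rng)
        xyz = rng.uniform(-1, 9, size=(300, 3))
        animals = rng.choice(["A1", "A2", "A3"], size=300)
        out = count_by_region(table_for(xyz, animals), vol)
        base = out[~out.overlay]
        assert base["n_pooled"].sum() == 300
        for a in ("A1", "A2", "A3"):
            assert base[f"n_{a}"].sum() == (animals == a).sum()

    def test_overlay_mask_rows_and_grid_mismatch(self, rng):
        vol = small_volume()
        mask = RegionMask(np.ones(vol.shape, dtype=bool), "everything")
        out = count_by_region(table_for([[1.0, 1.0, 1.0]]), vol, (mask,))
        row = out[out.overlay].iloc[0]
        assert row.region == "everything" and row.n_pooled == 1
        bad = RegionMask(np.ones((2, 2, 2), dtype=bool), "bad")
        with pytest.raises(GeometryError):
            count_by_region(table_for([[1.0, 1.0, 1.0]]), vol, (bad,))


class TestGroupPercentages:
    def test_single_group_hits_100(self):
        vol = small_volume()
        out = count_by_region(table_for([[0.5, 0.5, 0.5]] * 4), vol)
        gp = group_percentages(out).set_index("group")
        assert gp.loc["brainstem", "pct_pooled"] == 100.0

    def test_even_split(self):
        vol = small_volume()
        pts = [[0.5, 0.5, 0.5]] * 5 + [[4.5, 0.5, 0.5]] * 5
        gp = group_percentages(count_by_region(table_for(pts), vol)).set_index("group")
        assert gp.loc["brainstem", "pct_pooled"] == 50.0
        assert gp.loc["midbrain", "pct_pooled"] == 50.0

    def test_per_animal_mean_and_range_match_hand_computation(self):
        vol = small_volume()
        # A1: 3 brainstem, 1 midbrain; A2: 1 brainstem, 1 midbrain
        pts = [[0.5, 0, 0]] * 3 + [[4.5, 0, 0]] + [[0.5, 0, 0]] + [[4.5, 0, 0]]
        animals = ["A1"] * 4 + ["A2"] * 2
        gp = group_percentages(count_by_region(table_for(pts, animals), vol))
        gp = gp.set_index("group")
        assert gp.loc["brainstem", "pct_mean"] == pytest.approx((75.0 + 50.0) / 2)
        assert gp.loc["brainstem", "pct_min"] == 50.0
        assert gp.loc["brainstem", "pct_max"] == 75.0

    def test_region_without_group_is_config_error(self):
        vol = small_volume()
        out = count_by_region(table_for([[0.5, 0.5, 0.5]]), vol)
        out.loc[out.region == "r1", "group"] = ""
        with pytest.raises(ConfigError, match="r1"):
            group_percentages(out)


def with_starters(inputs_x, starters_x, animal="A1"):
    rows = []
    for x in inputs_x:
        rows.append({"animal_id": animal, "class": "input", "x": x, "y": 0.0, "z": 0.0})
    for x in starters_x:
        rows.append({"animal_id": animal, "class": "starter_C1", "x": x, "y": 0.0, "z": 0.0})
    return pd.DataFrame(rows)


class TestLaterality:
    def test_all_points_on_starter_side(self):
        df = with_starters([1.0, 2.0, 3.0], [2.0, 2.5])
        out = laterality(df, midline_x=10.0)
        assert out.ipsi_pct.iloc[0] == 100.0
        assert out.ipsi_side.iloc[0] == "left"

    def test_even_split_is_50(self):
        df = with_starters([1.0, 2.0, 18.0, 19.0], [2.0])
        out = laterality(df, midline_x=10.0)
        assert out.ipsi_pct.iloc[0] == 50.0

    def test_left_plus_right_reference_sums_to_100(self, rng):
        xs = rng.uniform(0, 20, size=50)
        xs = xs[np.abs(xs - 10.0) > 0.5]
        df = with_starters(xs, [1.0])
        left = laterality(df, 10.0, reference_side="left").ipsi_pct.iloc[0]
        right = laterality(df, 10.0, reference_side="right").ipsi_pct.iloc[0]
        assert left + right == pytest.approx(100.0)

    def test_midline_points_are_excluded(self):
        df = with_starters([1.0, 10.2, 9.9], [1.0])
        out = laterality(df, 10.0)
        assert out.n_indeterminate.iloc[0] == 2
        assert out.ipsi_pct.iloc[0] == 100.0

    def test_auto_mode_without_starters_raises(self):
        df = with_starters([1.0], [])
        with pytest.raises(ValueError, match="starter"):
            laterality(df, 10.0)


class TestEdgeLengths:
    def test_point_at_epicenter(self):
        assert edge_lengths(np.array([[1.0, 2.0, 3.0]]), (1, 2, 3))[0] == 0.0

    def test_pythagorean_offset(self):
        d = edge_lengths(np.array([[3.0, 4.0, 0.0]]), (0, 0, 0), voxel_size_um=39.0)
        assert d[0] == pytest.approx(0.195)

    def test_published_three_voxel_offset(self):
        # 3 voxels rostral at 39 µm = the printed 117 µm
        d = edge_lengths(np.array([[0.0, 3.0, 0.0]]), (0, 0, 0), voxel_size_um=39.0)
        assert d[0] * 1000 == pytest.approx(117.0)

    def test_invariant_under_joint_mirroring(self, rng):
        pts = rng.uniform(0, 100, size=(50, 3))
        epi = np.array([40.0, 50.0, 60.0])
        d0 = edge_lengths(pts, epi)
        mirrored = mirror_points(pts, 55.0)[50:]
        epi_m = np.array([2 * 55.0 - epi[0], epi[1], epi[2]])
        assert np.allclose(edge_lengths(mirrored, epi_m), d0)


class TestEdgeSummary:
    def test_all_zero_distances(self):
        s = edge_summary({"A1": np.zeros(5)}, thresholds_mm=(2.5, 5.0))
        assert s.median_mean_mm == 0.0
        assert s.frac_beyond[2.5] == 0.0 and s.frac_beyond[5.0] == 0.0

    def test_even_sample_median_is_midpoint(self):
        s = edge_summary({"A1": np.array([1.0, 2.0, 3.0, 4.0])}, thresholds_mm=(2.5,))
        assert s.per_animal_median_mm["A1"] == 2.5
        assert s.frac_beyond[2.5] == 0.5

    def test_mean_and_range_over_animals(self):
        s = edge_summary({"A1": np.array([1.0]), "A2": np.array([3.0])})
        assert s.median_mean_mm == 2.0
        assert (s.median_min_mm, s.median_max_mm) == (1.0, 3.0)

    def test_cdf_is_nondecreasing(self, rng):
        s = edge_summary({"A1": rng.exponential(2.0, size=200)})
        assert (np.diff(s.cdf_mm) >= 0).all()
        assert (np.diff(s.cdf_frac) >= 0).all()

    def test_empty_animal_named_in_error(self):
        with pytest.raises(ValueError, match="A2"):
            edge_summary({"A1": np.array([1.0]), "A2": np.array([])})
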