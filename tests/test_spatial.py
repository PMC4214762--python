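"""MCP home ranges, overlap, fidelity, regression, roost sharing."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPolygon, Point, Polygon, box

from roostnet import spatial
from conftest import make_records


def shoelace(vertices):
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestMCP:
    def test_unit_square(self):
        hr = spatial.mcp([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert hr.area_km2 == pytest.approx(1e-6)

    def test_right_triangle(self):
        hr = spatial.mcp([(0, 0), (4000, 0), (0, 3000)])
        assert hr.area_km2 == pytest.approx(6.0)

    def test_random_points_hull_contains_all_and_matches_shoelace(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 1000, size=(50, 2))
        hr = spatial.mcp(pts)
        for p in pts:
            assert hr.polygon.covers(Point(p))
        verts = np.asarray(hr.polygon.exterior.coords)[:-1]
        assert hr.area_m2 == pytest.approx(shoelace(verts), rel=1e-12)

    @pytest.mark.parametrize("bad", [[(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2), (3, 3)]])
    def test_degenerate_geometry_rejected(self, bad):
        with pytest.raises(spatial.DegenerateGeometryError):
            spatial.mcp(bad)

    def test_area_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 500, size=(20, 2))
        base = spatial.mcp(pts).area_km2
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + np.array([12345.0, -987.0])
        assert spatial.mcp(moved).area_km2 == pytest.approx(base, rel=1e-9)


class TestGroupRoostFilters:
    def _roosts(self, coords):
        return pd.DataFrame(
            [{"roost_id": f"R{i}", "x": x, "y": y} for i, (x, y) in enumerate(coords)]
        )

    def test_single_bat_roost_removed(self):
        # R4 only ever holds one group member; the 4 others hold pairs
        colonies = [(f"2006-06-0{i+1}", f"R{i}", ["a", "b"]) for i in range(4)]
        colonies.append(("2006-06-09", "R4", ["a"]))
        recs = make_records(colonies)
        roosts = self._roosts([(0, 0), (100, 0), (0, 100), (100, 100), (50, 50)])
        gr = spatial.prepare_group_roosts(recs, {"a": 0, "b": 0}, roosts)
        assert "R4" in gr[0].removed_single_use
        assert set(gr[0].roosts["roost_id"]) == {"R0", "R1", "R2", "R3"}
        assert not gr[0].excluded

    def test_isolated_roost_removed(self):
        colonies = [(f"2006-06-0{i+1}", f"R{i}", ["a", "b"]) for i in range(5)]
        recs = make_records(colonies)
        roosts = self._roosts([(0, 0), (100, 0), (0, 100), (100, 100), (1500, 1500)])
        gr = spatial.prepare_group_roosts(recs, {"a": 0, "b": 0}, roosts)
        assert gr[0].removed_isolated == ["R4"]
        assert not gr[0].excluded

    def test_three_or_fewer_roosts_excluded(self):
        colonies = [(f"2006-06-0{i+1}", f"R{i}", ["a", "b"]) for i in range(3)]
        recs = make_records(colonies)
        roosts = self._roosts([(0, 0), (100, 0), (0, 100)])
        gr = spatial.prepare_group_roosts(recs, {"a": 0, "b": 0}, roosts)
        assert gr[0].excluded
        assert "3 roosts" in gr[0].reason


class TestCropAndOverlap:
    def test_mask_superset_unchanged(self):
        hr = spatial.mcp([(0, 0), (0, 1000), (1000, 0), (1000, 1000)])
        out = spatial.crop_to_habitat(hr, box(-10, -10, 2000, 2000))
        assert out.area_km2 == pytest.approx(hr.area_km2)

    def test_half_mask_halves_area(self):
        hr = spatial.mcp([(0, 0), (0, 1000), (1000, 0), (1000, 1000)])
        out = spatial.crop_to_habitat(hr, box(0, 0, 500, 1000))
        assert out.area_km2 == pytest.approx(hr.area_km2 / 2)

    def test_multipart_mask_sums_pieces(self):
        hr = spatial.mcp([(0, 0), (0, 1000), (1000, 0), (1000, 1000)])
        mask = MultiPolygon([box(0, 0, 200, 1000), box(600, 0, 900, 1000)])
        out = spatial.crop_to_habitat(hr, mask)
        expected = (200 * 1000 + 300 * 1000) / 1e6
        assert out.area_km2 == pytest.approx(expected)

    def test_empty_intersection_zero_area(self, caplog):
        import logging

        hr = spatial.mcp([(0, 0), (0, 10), (10, 0)])
        with caplog.at_level(logging.WARNING, logger="roostnet"):
            out = spatial.crop_to_habitat(hr, box(100, 100, 200, 200))
        assert out.area_km2 == 0.0

    def _hr(self, poly, gid, sp):
        return spatial.HomeRange(gid, sp, poly, poly.area / 1e6)

    def test_disjoint_ranges_no_overlap(self):
        a = self._hr(box(0, 0, 10, 10), "A", "nattereri")
        b = self._hr(box(100, 0, 110, 10), "B", "nattereri")
        rep = spatial.overlap_stats([a, b])
        assert rep.intra_species_pct["nattereri"] == 0.0

    def test_identical_ranges_full_overlap(self):
        a = self._hr(box(0, 0, 10, 10), "A", "nattereri")
        b = self._hr(box(0, 0, 10, 10), "B", "nattereri")
        rep = spatial.overlap_stats([a, b])
        assert rep.intra_species_pct["nattereri"] == pytest.approx(100.0)
        assert rep.max_ranges_sharing_a_point == 2

    def test_interspecies_union_normalised(self):
        # two unit squares sharing half their area: 0.5 / 1.5
        a = self._hr(box(0, 0, 1, 1), "A", "nattereri")
        b = self._hr(box(0.5, 0, 1.5, 1), "B", "daubentonii")
        rep = spatial.overlap_stats([a, b])
        assert rep.inter_species_shared_pct_union == pytest.approx(100 * 0.5 / 1.5)
        assert rep.inter_species_shared_pct_by_species["nattereri"] == pytest.approx(50.0)
        # symmetric in species ordering
        rep2 = spatial.overlap_stats([b, a])
        assert rep2.inter_species_shared_pct_union == pytest.approx(
            rep.inter_species_shared_pct_union
        )

    def test_max_coverage_depth(self):
        polys = [box(0, 0, 4, 4), box(1, 1, 5, 5), box(2, 2, 6, 6), box(50, 50, 51, 51)]
        rngs = [self._hr(p, str(i), "nattereri") for i, p in enumerate(polys)]
        rep = spatial.overlap_stats(rngs)
        assert rep.max_ranges_sharing_a_point == 3


class TestFidelity:
    def test_all_inside(self):
        hr = spatial.mcp([(0, 0), (0, 100), (100, 0), (100, 100)])
        fixes = pd.DataFrame({"individual_id": "a", "date": "2006-08-01",
                              "x": [10, 50, 99], "y": [10, 50, 99]})
        res = spatial.range_fidelity(fixes, hr)
        assert res["pct_inside"] == 100.0

    def test_ten_metres_outside_in_15m_bucket(self):
        hr = spatial.mcp([(0, 0), (0, 100), (100, 0), (100, 100)])
        fixes = pd.DataFrame({"individual_id": "a", "date": "2006-08-01",
                              "x": [110.0], "y": [50.0]})
        res = spatial.range_fidelity(fixes, hr)
        assert res["pct_inside"] == 0.0
        assert res["pct_outside_within_15m"] == 100.0

    def test_mixed_fixture_matches_per_point_oracle(self):
        rng = np.random.default_rng(8)
        hr = spatial.mcp([(0, 0), (0, 100), (100, 0), (100, 100)])
        xy = rng.uniform(-50, 150, size=(20, 2))
        fixes = pd.DataFrame({"individual_id": "a", "date": "2006-08-01",
                              "x": xy[:, 0], "y": xy[:, 1]})
        res = spatial.range_fidelity(fixes, hr)
        inside = np.array([hr.polygon.covers(Point(p)) for p in xy])
        d = np.array([Point(p).distance(hr.polygon) for p in xy])
        n_out = (~inside).sum()
        assert res["pct_inside"] == pytest.approx(100 * inside.sum() / 20)
        assert res["pct_outside_within_15m"] == pytest.approx(
            100 * (d[~inside] <= 15).sum() / n_out
        )
        assert res["pct_outside_within_100m"] == pytest.approx(
            100 * (d[~inside] <= 100).sum() / n_out
        )

    def test_no_fixes_rejected(self):
        hr = spatial.mcp([(0, 0), (0, 10), (10, 0)])
        with pytest.raises(ValueError):
            spatial.range_fidelity(pd.DataFrame(columns=["x", "y"]), hr)


class TestAreaRegression:
    def test_noiseless_linear_recovery(self):
        sizes = np.array([5, 8, 11, 14, 20, 25, 30, 12, 9.0])
        areas = 0.02 * sizes
        species = ["nattereri"] * 5 + ["daubentonii"] * 4
        effort = np.array([1.0, 2, 1.5, 3, 2.5, 1, 2, 3, 1.2])
        res = spatial.area_regression(areas, sizes, species, effort).set_index("term")
        assert res.loc["group_size", "coef"] == pytest.approx(0.02, abs=1e-10)
        assert res.loc["group_size", "p"] < 0.001

    def test_constant_effort_rank_deficiency_named(self):
        sizes = np.arange(8.0, 16)
        with pytest.raises(ValueError, match="effort"):
            spatial.area_regression(
                0.02 * sizes + 0.1, sizes, ["nattereri"] * 8, np.full(8, 2.0)
            )

    def test_simulation_calibration_size_effect(self):
        """Planted positive size effect and null effort effect: the size
        term is detected in most runs, the effort term at around the
        nominal false-positive rate."""
        rng = np.random.default_rng(77)
        size_sig = effort_sig = 0
        n_runs = 50
        for _ in range(n_runs):
            n = 12
            sizes = rng.uniform(5, 30, n)
            effort = rng.uniform(1, 4, n)
            species = np.where(rng.uniform(size=n) < 0.5, "nattereri", "daubentonii")
            areas = 0.01 * sizes + rng.normal(0, 0.05, n)
            res = spatial.area_regression(areas, sizes, species, effort).set_index("term")
            size_sig += res.loc["group_size", "p"] < 0.05
            effort_sig += res.loc["effort", "p"] < 0.05
        assert size_sig / n_runs > 0.8
        assert effort_sig / n_runs <= 0.16  # ~5% nominal, 99% binomial slack


class TestRoostSharing:
    def test_chi2_zero_when_observed_equals_expected(self):
        res = spatial.roost_sharing_test(100, 100, 50, 200)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # (shared, A only, B only, neither) = (10, 40, 40, 110), N = 200
        res = spatial.roost_sharing_test(50, 50, 10, 200)
        table = np.array([[10, 40], [40, 110]], dtype=float)
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - exp) ** 2 / exp).sum()
        assert res["chi2"] == pytest.approx(chi2, rel=1e-12)
        assert res["df"] == 1

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            spatial.roost_sharing_test(5, 8, 6, 100)
        with pytest.raises(ValueError):
            spatial.roost_sharing_test(80, 80, 10, 100)


class TestSyntheticGeometry:
    def test_disjoint_clusters_zero_overlap_and_truth_roosts_inside(self):
        """Spatially disjoint planted roost clusters give 0% intra-species
        overlap, and every filtered truth roost lies in its group's MCP."""
        from roostnet import simulate

        cfg = simulate.SimulationConfig(seed=5, survey_prob=0.4)
        caps, roosts, truth = simulate.simulate_population(cfg)
        part = {i: g for i, g in truth.group_of.items() if i in set(caps["individual_id"])}
        by_sp = {}
        for sp in ("nattereri", "daubentonii"):
            recs = caps[caps["species"] == sp]
            sub_part = {i: g for i, g in part.items() if truth.group_species[g] == sp}
            gr = spatial.prepare_group_roosts(recs, sub_part, roosts)
            rngs = spatial.ranges_from_groups(gr)
            by_sp[sp] = rngs
            coords = roosts.set_index("roost_id")
            for r in rngs:
                for rid in r.roost_ids:
                    p = Point(coords.loc[rid, "x"], coords.loc[rid, "y"])
                    assert r.polygon.covers(p)
        all_ranges = by_sp["nattereri"] + by_sp["daubentonii"]
        if len(all_ranges) >= 2:
            rep = spatial.overlap_stats(all_ranges)
            for sp, pct in rep.intra_species_pct.items():
                assert pct == 0.0
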