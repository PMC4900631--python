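"""LoCoH hull construction, isopleths, overlap decomposition and the
spatial gregariousness indices, checked against hand geometry and a grid
rasterization oracle."""

import numpy as np
import pytest
from shapely.geometry import box, Point

from fisofus.errors import ConfigurationError, EstimationError, InsufficientDataError
from fisofus.scan_io import FocalRoster
from fisofus.space_use import (
    CoreArea, Isopleth, build_hulls_adaptive, isopleth_from_hulls, core_area,
    a_selection_diagnostics, overlap_decomposition,
    group_spatial_gregariousness, individual_spatial_gregariousness,
    isgi_by_sex, core_area_to_geojson,
)

import conftest
from conftest import make_table


def raster_multiplicity_areas(regions, bounds, res=0.01):
    """Grid oracle: per-multiplicity areas (in the regions' native units^2)
    by counting cell centres covered by exactly i regions."""
    minx, miny, maxx, maxy = bounds
    xs = np.arange(minx + res / 2, maxx, res)
    ys = np.arange(miny + res / 2, maxy, res)
    gx, gy = np.meshgrid(xs, ys)
    import shapely
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    counts = np.zeros(len(pts), dtype=int)
    for r in regions:
        counts += shapely.covers(r, pts).astype(int)
    cell = res * res
    return {i: float((counts == i).sum()) * cell
            for i in range(1, len(regions) + 1)}


def make_core(geom, ind="X", season="dry-2013"):
    iso = Isopleth(0.6, geom, geom.area / 1e4, 1, 1)
    return CoreArea(ind, season, iso, 10, 100.0)


class TestHulls:
    def test_cumulative_distance_inclusion_rule(self):
        # neighbours at 10, 20, 40 m; a=35 admits the two nearest (10+20=30)
        pts = np.array([[0, 0], [10, 0], [0, 20], [40, 0]])
        hulls = build_hulls_adaptive(pts, a=35)
        h0 = hulls[0]
        assert set(h0.neighbor_indices) == {1, 2}
        assert not h0.degenerate

    def test_a_below_nearest_neighbour_gives_degenerate_singleton(self):
        pts = np.array([[0, 0], [50, 0], [0, 50], [50, 50]])
        hulls = build_hulls_adaptive(pts, a=10)
        assert all(h.degenerate for h in hulls)
        assert all(len(h.neighbor_indices) == 0 for h in hulls)

    def test_all_identical_points_warn_but_do_not_raise(self):
        pts = np.zeros((5, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            hulls = build_hulls_adaptive(pts, a=10)
        assert all(h.degenerate for h in hulls)

    def test_too_few_points_raise(self):
        with pytest.raises(InsufficientDataError):
            build_hulls_adaptive(np.array([[0, 0], [1, 1]]), a=10)

    def test_enclosed_count_counts_boundary(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [5, 2]])
        hulls = build_hulls_adaptive(pts, a=100)
        # the full-triangle hull encloses all four points (boundary included)
        assert max(h.enclosed_count for h in hulls) == 4


class TestIsopleth:
    def _uniform_cloud(self, n=200, side=100.0, seed=5):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, side, size=(n, 2))

    def test_full_level_covers_every_point(self):
        pts = self._uniform_cloud(50)
        hulls = build_hulls_adaptive(pts, a=80)
        iso = isopleth_from_hulls(hulls, 1.0, points=pts)
        assert iso.points_covered == len(pts)

    def test_level_guarantee(self):
        pts = self._uniform_cloud(101)
        hulls = build_hulls_adaptive(pts, a=60)
        iso = isopleth_from_hulls(hulls, 0.6, points=pts)
        assert iso.points_covered >= int(np.ceil(0.6 * len(pts)))

    def test_nestedness_and_bounding_area(self):
        pts = self._uniform_cloud(200)
        hulls = build_hulls_adaptive(pts, a=200)
        areas = {}
        regions = {}
        for lv in (0.4, 0.6, 1.0):
            iso = isopleth_from_hulls(hulls, lv, points=pts)
            areas[lv], regions[lv] = iso.area_ha, iso.region
        assert areas[0.4] <= areas[0.6] <= areas[1.0] <= 1.0 + 0.01
        # nested regions (within geometric tolerance)
        assert regions[0.4].difference(regions[0.6]).area < 1e-6
        assert regions[0.6].difference(regions[1.0]).area < 1e-6

    def test_all_degenerate_raises(self):
        pts = np.array([[0, 0], [0, 0], [0, 0]])
        with pytest.warns(UserWarning):
            hulls = build_hulls_adaptive(pts, a=5)
        with pytest.raises(EstimationError):
            isopleth_from_hulls(hulls, 0.6)

    def test_bad_level_rejected(self):
        with pytest.raises(ConfigurationError):
            isopleth_from_hulls([], 0.0)


class TestCoreArea:
    def _two_cluster_table(self):
        rng = np.random.default_rng(3)
        rows = []
        for k in range(12):
            x, y = rng.normal(0, 5, 2)
            rows.append((f"2013-01-{k+1:02d}", "08:00", f"S{k}", x, y, "A"))
        for k in range(12):
            x, y = rng.normal([5000, 5000], 5).tolist()
            rows.append((f"2013-02-{k+1:02d}", "08:00", f"T{k}", x, y, "A"))
        return make_table(rows)

    def test_two_far_clusters_with_small_a_give_multipart_region(self):
        t = self._two_cluster_table()
        ca = core_area(t, "A", "dry-2013", a=60, level=0.9)
        assert ca.region.geom_type == "MultiPolygon"
        assert len(ca.region.geoms) >= 2

    def test_determinism_on_identical_cloud(self):
        t = self._two_cluster_table()
        c1 = core_area(t, "A", "dry-2013", a=60)
        c2 = core_area(t, "A", "dry-2013", a=60)
        assert c1.area_ha == c2.area_ha
        assert c1.region.equals(c2.region)

    def test_insufficient_sightings_named(self):
        t = self._two_cluster_table()
        with pytest.raises(InsufficientDataError, match="A.*wet-2013|wet-2013.*A"):
            core_area(t, "A", "wet-2013", a=60)

    def test_geojson_export_round_numbers(self):
        t = self._two_cluster_table()
        ca = core_area(t, "A", "dry-2013", a=60)
        gj = core_area_to_geojson([ca])
        props = gj["features"][0]["properties"]
        assert props["individual_id"] == "A"
        assert props["area_ha"] == pytest.approx(ca.area_ha)


class TestASelectionDiagnostics:
    def test_single_candidate_single_row(self):
        pts = np.random.default_rng(0).uniform(0, 100, (40, 2))
        rows = a_selection_diagnostics(pts, [50])
        assert len(rows) == 1 and rows[0]["a"] == 50

    def test_patch_count_non_increasing_in_a(self):
        pts = np.random.default_rng(1).uniform(0, 100, (60, 2))
        rows = a_selection_diagnostics(pts, [20, 60, 150, 400])
        counts = [r["patch_count"] for r in rows]
        assert counts == sorted(counts, reverse=True)

    def test_tiny_a_stays_clear_of_distant_barrier(self):
        pts = np.random.default_rng(2).uniform(0, 100, (40, 2))
        barrier = box(1000, -1000, 5000, 5000)
        rows = a_selection_diagnostics(pts, [15], barriers=[barrier])
        assert rows[0]["barrier_intersection_ha"] == pytest.approx(0.0)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ConfigurationError):
            a_selection_diagnostics(np.zeros((5, 2)), [])


UNIT = 100.0  # 1 "unit square" drawn as 100 m x 100 m = 1 ha


class TestOverlapDecomposition:
    def test_identical_squares(self):
        sq = box(0, 0, UNIT, UNIT)
        d = overlap_decomposition([sq] * 4)
        assert d.union_area_ha == pytest.approx(1.0)
        assert d.per_multiplicity[4] == pytest.approx(1.0)
        assert all(d.per_multiplicity[i] == pytest.approx(0.0) for i in (1, 2, 3))

    def test_three_disjoint_squares(self):
        sqs = [box(300 * k, 0, 300 * k + UNIT, UNIT) for k in range(3)]
        d = overlap_decomposition(sqs)
        assert d.union_area_ha == pytest.approx(3.0)
        assert d.per_multiplicity[1] == pytest.approx(3.0)

    def test_half_overlap_plus_disjoint(self):
        a = box(0, 0, UNIT, UNIT)
        b = box(UNIT / 2, 0, 3 * UNIT / 2, UNIT)  # overlaps a by 0.5
        c = box(1000, 0, 1000 + UNIT, UNIT)
        d = overlap_decomposition([a, b, c])
        assert d.union_area_ha == pytest.approx(2.5)
        assert d.per_multiplicity[1] == pytest.approx(2.0)
        assert d.per_multiplicity[2] == pytest.approx(0.5)

    def test_conservation_and_raster_oracle_on_random_boxes(self, rng):
        for _ in range(5):
            boxes = []
            for _ in range(4):
                x, y = rng.uniform(0, 5, 2)
                w, h = rng.uniform(1, 4, 2)
                boxes.append(box(x, y, x + w, y + h))
            d = overlap_decomposition(boxes)
            assert sum(d.per_multiplicity.values()) == pytest.approx(
                d.union_area_ha, rel=1e-6)
            oracle = raster_multiplicity_areas(boxes, (0, 0, 10, 10), res=0.02)
            for i in range(1, 5):
                got = d.per_multiplicity[i] * 1e4  # back to native units
                assert got == pytest.approx(oracle[i], abs=0.02 * max(1.0, got))

    def test_mixed_seasons_rejected(self):
        a = make_core(box(0, 0, 1, 1), "A", "dry-2013")
        b = make_core(box(0, 0, 1, 1), "B", "wet-2013")
        with pytest.raises(ConfigurationError, match="season"):
            overlap_decomposition([a, b])


class TestGregariousnessIndices:
    def test_gsgi_identical_is_one(self):
        d = overlap_decomposition([box(0, 0, UNIT, UNIT)] * 5)
        assert group_spatial_gregariousness(d) == pytest.approx(1.0)

    def test_gsgi_disjoint_is_zero(self):
        sqs = [box(400 * k, 0, 400 * k + UNIT, UNIT) for k in range(3)]
        assert group_spatial_gregariousness(overlap_decomposition(sqs)) == 0.0

    def test_gsgi_two_coincident_one_disjoint_is_one_third(self):
        sq = box(0, 0, UNIT, UNIT)
        far = box(1000, 0, 1000 + UNIT, UNIT)
        d = overlap_decomposition([sq, sq, far])
        # A = 2, O_2 = 1 -> (2*1)/(3*2)
        assert group_spatial_gregariousness(d) == pytest.approx(1 / 3)

    def test_isgi_identical_is_one(self):
        sq = box(0, 0, UNIT, UNIT)
        assert individual_spatial_gregariousness(sq, [sq, sq]) == pytest.approx(1.0)

    def test_isgi_disjoint_is_zero(self):
        sq = box(0, 0, UNIT, UNIT)
        far = box(1000, 0, 1000 + UNIT, UNIT)
        assert individual_spatial_gregariousness(sq, [far]) == 0.0

    def test_isgi_half_overlap(self):
        sq = box(0, 0, UNIT, UNIT)
        half = box(UNIT / 2, 0, 3 * UNIT / 2, UNIT)
        # K=2, O_2x = 0.5 -> (2*0.5)/(2*1)
        assert individual_spatial_gregariousness(sq, [half]) == pytest.approx(0.5)

    def test_indices_bounded_on_random_fixtures(self, rng):
        for _ in range(20):
            boxes = []
            for _ in range(rng.integers(2, 6)):
                x, y = rng.uniform(0, 300, 2)
                w, h = rng.uniform(50, 200, 2)
                boxes.append(box(x, y, x + w, y + h))
            d = overlap_decomposition(boxes)
            g = group_spatial_gregariousness(d)
            assert 0.0 <= g <= 1.0 + 1e-9
            i0 = individual_spatial_gregariousness(boxes[0], boxes[1:])
            assert 0.0 <= i0 <= 1.0 + 1e-9

    def test_isgi_against_raster_oracle(self, rng):
        sq = box(0, 0, 4, 4)
        others = [box(2, 1, 7, 5), box(-1, -1, 3, 3)]
        got = individual_spatial_gregariousness(sq, others)
        oracle = raster_multiplicity_areas([sq] + others, (-2, -2, 8, 8), res=0.01)
        # clip to A_x by rasterizing with the focal region as reference
        import shapely
        xs = np.arange(0.005, 4, 0.01)
        gx, gy = np.meshgrid(xs, xs)
        pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
        counts = np.ones(len(pts), dtype=int)
        for r in others:
            counts += shapely.covers(r, pts).astype(int)
        num = sum(i * (counts == i).sum() * 1e-4 for i in range(2, 4))
        expected = num / (3 * sq.area)
        assert got == pytest.approx(expected, rel=0.01)


class TestIsgiBySex:
    def _roster(self, sexes):
        import pandas as pd
        return FocalRoster(sorted(sexes), pd.DataFrame(), dict(sexes))

    def test_two_identical_males(self):
        sq = box(0, 0, UNIT, UNIT)
        cas = [make_core(sq, "M1"), make_core(sq, "M2")]
        r = self._roster({"M1": "male", "M2": "male"})
        vals = isgi_by_sex(cas, r)
        assert vals["M1"] == pytest.approx(1.0)
        assert vals["M2"] == pytest.approx(1.0)

    def test_male_overlapping_only_females_scores_zero(self):
        sq = box(0, 0, UNIT, UNIT)
        far = box(1000, 0, 1000 + UNIT, UNIT)
        cas = [make_core(sq, "M1"), make_core(far, "M2"), make_core(sq, "F1"),
               make_core(sq, "F2")]
        r = self._roster({"M1": "male", "M2": "male", "F1": "female",
                          "F2": "female"})
        vals = isgi_by_sex(cas, r)
        assert vals["M1"] == 0.0  # disjoint from the only other male

    def test_singleton_sex_class_is_missing(self):
        sq = box(0, 0, UNIT, UNIT)
        cas = [make_core(sq, "M1"), make_core(sq, "F1"), make_core(sq, "F2")]
        r = self._roster({"M1": "male", "F1": "female", "F2": "female"})
        assert isgi_by_sex(cas, r)["M1"] is None
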