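"""Projection accuracy, range-polygon construction, and contact analysis."""

import math

import numpy as np
import pytest
from shapely.geometry import Point

from arcticum import datasets
from arcticum.georange import (
    AlbersEqualArea,
    BUFFER_RADIUS_M,
    RangeMethod,
    build_range_polygon,
    pairwise_contact_matrix,
    project_points,
    ranges_to_geojson,
    sympatry_census,
    sympatry_census_from_counts,
)
from arcticum.records import Accuracy, Rank, Site


class TestProjection:
    def test_round_trip_survey_coordinates(self):
        proj = AlbersEqualArea()
        lon0, lat0 = -145.647495, 63.959281
        lon, lat = proj.inverse(*proj.forward(lon0, lat0))
        assert abs(lon - lon0) < 1e-6 and abs(lat - lat0) < 1e-6

    def test_central_meridian_maps_to_false_easting(self):
        proj = AlbersEqualArea()
        x, _ = proj.forward(proj.lon_origin, 52.0)
        assert x == pytest.approx(proj.false_easting, abs=1e-9)

    def test_round_trip_random_points(self):
        rng = np.random.default_rng(1)
        lon = rng.uniform(-170, -50, 100)
        lat = rng.uniform(15, 75, 100)
        proj = AlbersEqualArea()
        lon2, lat2 = proj.inverse(*proj.forward(lon, lat))
        assert np.max(np.abs(lon2 - lon)) < 1e-6
        assert np.max(np.abs(lat2 - lat)) < 1e-6

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AlbersEqualArea().forward(0.0, 95.0)

    def test_project_points_county_centroid_filter(self):
        sites = [
            Site("a", "", 50.0, -110.0, Accuracy.GPS),
            Site("b", "", 51.0, -111.0, Accuracy.COUNTY_CENTROID),
        ]
        assert project_points(sites).shape == (2, 2)
        assert project_points(sites, exclude_county_centroids=True).shape == (1, 2)


def shoelace(coords):
    x, y = np.asarray(coords).T
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestRangePolygon:
    def test_single_site_disc(self):
        rp = build_range_polygon("t", np.array([[0.0, 0.0]]))
        assert rp.method is RangeMethod.BUFFER_5KM
        assert rp.area_km2 == pytest.approx(math.pi * 25.0, rel=1e-4)
        assert round(rp.area_km2) == 79

    def test_unit_square_hull(self):
        pts = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], dtype=float)
        rp = build_range_polygon("t", pts)
        assert rp.method is RangeMethod.CONVEX_HULL
        assert rp.area_km2 == pytest.approx(1.0)

    def test_hull_area_matches_shoelace_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.uniform(0, 1e6, size=(50, 2))
            rp = build_range_polygon("t", pts)
            oracle = shoelace(rp.polygon.exterior.coords[:-1])
            assert rp.polygon.area == pytest.approx(oracle, rel=1e-9)

    def test_hull_contains_generating_points(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1e5, size=(30, 2))
        rp = build_range_polygon("t", pts)
        buffered = rp.polygon.buffer(1e-6)  # boundary-inclusive test
        assert all(buffered.contains(Point(p)) for p in pts)

    def test_two_points_buffered_segment(self):
        pts = np.array([[0.0, 0.0], [10_000.0, 0.0]])
        rp = build_range_polygon("t", pts)
        assert rp.method is RangeMethod.BUFFER_5KM
        expected = (10_000 * 2 * BUFFER_RADIUS_M + math.pi * BUFFER_RADIUS_M**2) / 1e6
        assert rp.area_km2 == pytest.approx(expected, rel=1e-4)

    def test_collinear_points_fall_back_to_buffer(self):
        pts = np.array([[0.0, 0.0], [5_000.0, 5_000.0], [10_000.0, 10_000.0]])
        rp = build_range_polygon("t", pts)
        assert rp.method is RangeMethod.BUFFER_5KM
        assert rp.area_km2 > 0

    def test_buffer_monotone_in_radius(self):
        pts = np.array([[0.0, 0.0], [8_000.0, 0.0]])
        a1 = build_range_polygon("t", pts, buffer_radius_m=2_000).area_km2
        a2 = build_range_polygon("t", pts, buffer_radius_m=5_000).area_km2
        assert a1 < a2

    def test_area_invariant_under_translation(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 1e5, size=(20, 2))
        a = build_range_polygon("t", pts).area_km2
        b = build_range_polygon("t", pts + np.array([3e6, -2e6])).area_km2
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_locations_rejected(self):
        with pytest.raises(ValueError):
            build_range_polygon("t", np.empty((0, 2)))

    def test_mask_clipping(self):
        from shapely.geometry import box

        rp = build_range_polygon(
            "t", np.array([[0.0, 0.0]]), mask=box(0, -1e5, 1e5, 1e5)
        )
        assert rp.area_km2 == pytest.approx(math.pi * 25.0 / 2, rel=1e-3)


def _disc(taxon, x, y, rank=Rank.CYTOTYPE, r=BUFFER_RADIUS_M):
    return build_range_polygon(taxon, np.array([[x, y]]), rank=rank,
                               buffer_radius_m=r)


class TestContactMatrix:
    def test_disjoint_discs_no_contact(self):
        m = pairwise_contact_matrix([_disc("a", 0, 0), _disc("b", 20_000, 0)])
        assert not m.contact("a", "b")

    def test_overlapping_discs_contact_symmetric(self):
        m = pairwise_contact_matrix([_disc("a", 0, 0), _disc("b", 2_000, 0)])
        assert m.contact("a", "b") and m.contact("b", "a")
        assert np.array_equal(m.matrix, m.matrix.T)
        assert not m.matrix.diagonal().any()

    def test_counts_match_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        ranges = []
        for i in range(12):
            x, y = rng.uniform(0, 60_000, 2)
            rank = Rank.SIBLING if i < 4 else Rank.CYTOTYPE
            ranges.append(_disc(f"t{i}", x, y, rank, r=rng.uniform(3e3, 12e3)))
        m = pairwise_contact_matrix(ranges)
        # O(n^2) shapely-free oracle: discs touch iff centre distance <= r1+r2
        centres = [r.polygon.centroid for r in ranges]
        radii = [math.sqrt(r.polygon.area / math.pi) for r in ranges]
        for i in range(12):
            for j in range(i + 1, 12):
                d = centres[i].distance(centres[j])
                expected = d <= radii[i] + radii[j] + 1.0  # polygonal slack
                strict = d <= radii[i] + radii[j] - 1.0
                if strict:
                    assert m.matrix[i, j]
                elif not expected:
                    assert not m.matrix[i, j]

    def test_fewer_than_two_ranges_rejected(self):
        with pytest.raises(ValueError):
            pairwise_contact_matrix([_disc("a", 0, 0)])


class TestSympatryCensus:
    def test_published_contact_columns(self):
        census = sympatry_census_from_counts(datasets.range_contact_summary())
        assert census.n_cytotypes_with_sibling_contact == 21
        assert census.n_cytotypes_total == 22
        gm = census.group_means
        assert gm.loc["sibling_vs_sibling", "n"] == 9
        assert gm.loc["cytotype_vs_sibling", "n"] == 22
        # siblings have larger ranges, so they contact more cytotypes than
        # cytotypes contact siblings
        assert (
            gm.loc["sibling_vs_cytotype", "mean"]
            > gm.loc["cytotype_vs_sibling", "mean"]
        )

    def test_all_disjoint_ranges(self):
        ranges = [
            _disc("s", 0, 0, Rank.SIBLING),
            _disc("c1", 50_000, 0),
            _disc("c2", 100_000, 0),
        ]
        census = sympatry_census(pairwise_contact_matrix(ranges))
        assert census.n_cytotypes_with_sibling_contact == 0
        assert census.n_cytotypes_total == 2

    def test_nested_construction_full_sympatry(self):
        rng = np.random.default_rng(3)
        sib = build_range_polygon(
            "sib", rng.uniform(0, 5e5, size=(20, 2)), rank=Rank.SIBLING
        )
        ranges = [sib]
        minx, miny, maxx, maxy = sib.polygon.bounds
        made = 0
        while made < 6:
            x, y = rng.uniform(minx, maxx), rng.uniform(miny, maxy)
            if sib.polygon.contains(Point(x, y)):
                ranges.append(_disc(f"c{made}", x, y))
                made += 1
        census = sympatry_census(pairwise_contact_matrix(ranges))
        assert census.n_cytotypes_with_sibling_contact == 6
        assert census.n_cytotypes_total == 6


def test_geojson_export_round_trips_coordinates():
    proj = AlbersEqualArea()
    x, y = proj.forward(-120.0, 50.0)
    rp = _disc("t", float(x), float(y))
    gj = ranges_to_geojson([rp])
    assert gj["type"] == "FeatureCollection"
    feat = gj["features"][0]
    assert feat["properties"]["taxon"] == "t"
    lons, lats = zip(*feat["geometry"]["coordinates"][0])
    assert abs(np.mean(lons) - (-120.0)) < 0.01
    assert abs(np.mean(lats) - 50.0) < 0.01
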