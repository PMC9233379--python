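"""Exclusion rules, block assignment, rates, facility distances,
projection of incident points."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from spatclust.core import TEN_MILES_M, ConfigurationError
from spatclust.ingest import (assign_to_blocks, compute_rates,
                              filter_incidents, nearest_facility_distance,
                              project_points)
from spatclust.projection import geographic_to_utm

from conftest import lattice_blocks

ASSOC = {"OD-CONFIRMED"}


def make_records(rows):
    return pd.DataFrame(rows, columns=["record_id", "lon", "lat", "timestamp",
                                       "disposition_code", "cancelled_flag"])


@pytest.fixture
def contaminated_fixture():
    """5 clean records plus 1 missing geocode, 1 outside the window,
    1 unassociated code, 1 cancelled, and 2 exact duplicates of retained
    records (11 rows; the tally must partition them as 5 + (1,1,1,1,2))."""
    clean = [
        ("r0", 0.1, 0.1, "2016-01-01", "OD-CONFIRMED", False),
        ("r1", 0.3, 0.4, "2016-02-01", "OD-CONFIRMED", False),
        ("r2", 0.5, 0.5, "2016-03-01", "OD-CONFIRMED", False),
        ("r3", 0.7, 0.2, "2016-04-01", "OD-CONFIRMED", False),
        ("r4", 0.9, 0.9, "2016-05-01", "OD-CONFIRMED", False),
    ]
    bad = [
        ("r5", np.nan, np.nan, "2016-06-01", "OD-CONFIRMED", False),
        ("r6", 3.0, 0.5, "2016-07-01", "OD-CONFIRMED", False),
        ("r7", 0.2, 0.2, "2016-08-01", "OTHER", False),
        ("r8", 0.4, 0.4, "2016-09-01", "OD-CONFIRMED", True),
        ("r0", 0.1, 0.1, "2016-01-01", "OD-CONFIRMED", False),  # dup of r0
        ("r1", 0.3, 0.4, "2016-02-01", "OD-CONFIRMED", False),  # dup of r1
    ]
    return make_records(clean + bad)


class TestFilter:
    def test_ten_record_fixture(self, contaminated_fixture, unit_square):
        retained, tally = filter_incidents(contaminated_fixture, unit_square,
                                           ASSOC)
        assert len(retained) == 5
        assert tally.missing_geocode == 1
        assert tally.outside_area == 1
        assert tally.unassociated_disposition == 1
        assert tally.cancelled_or_false_alarm == 1
        assert tally.duplicate == 2
        assert tally.retained == 5
        assert tally.total == len(contaminated_fixture)

    def test_all_clean_passthrough(self, unit_square):
        df = make_records([
            ("a", 0.2, 0.2, "t1", "OD-CONFIRMED", False),
            ("b", 0.8, 0.3, "t2", "OD-CONFIRMED", False),
        ])
        retained, tally = filter_incidents(df, unit_square, ASSOC)
        assert len(retained) == 2
        assert tally.excluded == 0

    def test_empty_disposition_set_error(self, unit_square):
        with pytest.raises(ConfigurationError):
            filter_incidents(make_records([]), unit_square, set())

    def test_idempotence(self, contaminated_fixture, unit_square):
        once, _ = filter_incidents(contaminated_fixture, unit_square, ASSOC)
        twice, tally2 = filter_incidents(once, unit_square, ASSOC)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))
        assert tally2.excluded == 0

    def test_tally_partition_random_contamination(self, unit_square, rng):
        # property: retained + sum(reasons) == input size for arbitrary mixes
        for rep in range(10):
            n = int(rng.integers(5, 40))
            rows = []
            for i in range(n):
                kind = rng.integers(0, 5)
                lon, lat = rng.uniform(0.05, 0.95, 2)
                rec = [f"x{i}", lon, lat, f"t{i}", "OD-CONFIRMED", False]
                if kind == 1:
                    rec[1] = rec[2] = np.nan
                elif kind == 2:
                    rec[1] = 5.0
                elif kind == 3:
                    rec[4] = "OTHER"
                elif kind == 4:
                    rec[5] = True
                rows.append(tuple(rec))
            df = make_records(rows)
            _, tally = filter_incidents(df, unit_square, ASSOC)
            assert tally.total == n

    def test_duplicate_by_record_id_only(self, unit_square):
        df = make_records([
            ("a", 0.2, 0.2, "t1", "OD-CONFIRMED", False),
            ("a", 0.6, 0.6, "t9", "OD-CONFIRMED", False),  # same id, new data
        ])
        retained, tally = filter_incidents(df, unit_square, ASSOC)
        assert tally.duplicate == 1
        assert retained["lat"].tolist() == [0.2]

    def test_duplicate_by_geocode_triple(self, unit_square):
        df = make_records([
            ("a", 0.2, 0.2, "t1", "OD-CONFIRMED", False),
            ("b", 0.2, 0.2, "t1", "OD-CONFIRMED", False),  # new id, same data
        ])
        _, tally = filter_incidents(df, unit_square, ASSOC)
        assert tally.duplicate == 1


class TestAssign:
    def test_interior_point(self):
        blocks = lattice_blocks(2, 2)
        df = make_records([("a", 0.5, 0.5, "t", "OD-CONFIRMED", False)])
        counts = assign_to_blocks(df, blocks)
        assert counts["b000000"] == 1
        assert counts.sum() == 1

    def test_boundary_tie_break_lowest_id(self):
        blocks = lattice_blocks(2, 2)
        # (1, 1) is the shared corner of all four blocks
        df = make_records([("a", 1.0, 1.0, "t", "OD-CONFIRMED", False)])
        counts = assign_to_blocks(df, blocks)
        assert counts["b000000"] == 1
        assert counts.sum() == 1

    def test_counts_sum_to_n(self, rng):
        blocks = lattice_blocks(2, 2)
        pts = rng.uniform(0.001, 1.999, (200, 2))
        df = make_records([
            (f"r{i}", x, y, "t", "OD-CONFIRMED", False)
            for i, (x, y) in enumerate(pts)])
        counts = assign_to_blocks(df, blocks)
        assert counts.sum() == 200
        # independent oracle: direct point-in-polygon count per block
        for bid, geom in zip(blocks.ids, blocks.geometries):
            expected = sum(
                1 for i, (x, y) in enumerate(pts)
                if geom.covers(Point(x, y))
                and not any(
                    blocks.geometries[k].covers(Point(x, y))
                    for k in range(len(blocks.ids))
                    if blocks.ids[k] < bid))
            assert counts[bid] == expected

    def test_outside_all_blocks_hard_error(self):
        blocks = lattice_blocks(2, 2)
        df = make_records([("a", 9.0, 9.0, "t", "OD-CONFIRMED", False)])
        with pytest.raises(ValueError, match="outside every block"):
            assign_to_blocks(df, blocks)


class TestRates:
    def test_arithmetic_identity(self):
        blocks = lattice_blocks(1, 4)
        blocks.data["adult_population"] = [2000, 1000, 500, 0]
        counts = pd.Series([12, 0, 5, 3], index=blocks.ids)
        rates = compute_rates(counts, blocks, n_years=6)
        assert rates.loc["b000000", "incident_rate"] == pytest.approx(1.0)
        assert rates.loc["b000001", "incident_rate"] == 0.0
        assert rates.loc["b000002", "incident_rate"] == pytest.approx(
            5 / 6 / 500 * 1000)

    def test_zero_population_excluded_and_reported(self):
        blocks = lattice_blocks(1, 4)
        blocks.data["adult_population"] = [2000, 1000, 500, 0]
        rates = compute_rates(pd.Series(1, index=blocks.ids), blocks, 1)
        assert "b000003" not in rates.index
        assert rates.attrs["excluded_zero_population"] == ["b000003"]

    def test_scale_equivariance(self, rng):
        blocks = lattice_blocks(2, 3)
        blocks.data["adult_population"] = rng.integers(100, 5000, 6)
        counts = pd.Series(rng.integers(0, 50, 6), index=blocks.ids)
        r1 = compute_rates(counts, blocks, 5)["incident_rate"]
        blocks.data["adult_population"] *= 2
        r2 = compute_rates(counts, blocks, 5)["incident_rate"]
        pd.testing.assert_series_equal(r1, r2 * 2)

    def test_invalid_years(self):
        blocks = lattice_blocks(2, 2)
        with pytest.raises(ValueError):
            compute_rates(pd.Series(0, index=blocks.ids), blocks, 0)


class TestFacilityDistance:
    def test_facility_at_centroid(self):
        blocks = lattice_blocks(1, 1, cell=1000.0)
        fac = pd.DataFrame([("f0", "hospital", 500.0, 500.0)],
                           columns=["facility_id", "facility_type", "lon", "lat"])
        d = nearest_facility_distance(blocks, fac)
        assert d.loc["b000000", "dist_hospital"] == 0.0

    def test_ten_mile_unit(self):
        blocks = lattice_blocks(1, 1, cell=1000.0)
        fac = pd.DataFrame([("f0", "otp", 500.0 + TEN_MILES_M, 500.0)],
                           columns=["facility_id", "facility_type", "lon", "lat"])
        d = nearest_facility_distance(blocks, fac)
        assert d.loc["b000000", "dist_otp"] == pytest.approx(1.0)

    def test_minimum_over_five_matches_brute_force(self, rng):
        blocks = lattice_blocks(3, 3, cell=1000.0)
        fxy = rng.uniform(0, 3000, (5, 2))
        fac = pd.DataFrame(
            [(f"f{i}", "hospital", x, y) for i, (x, y) in enumerate(fxy)],
            columns=["facility_id", "facility_type", "lon", "lat"])
        d = nearest_facility_distance(blocks, fac)
        for bid, geom in zip(blocks.ids, blocks.geometries):
            c = geom.centroid
            brute = min(np.hypot(c.x - x, c.y - y) for x, y in fxy)
            assert d.loc[bid, "dist_hospital"] == pytest.approx(
                brute / TEN_MILES_M)

    def test_empty_type_flagged(self):
        blocks = lattice_blocks(1, 1)
        fac = pd.DataFrame(columns=["facility_id", "facility_type", "lon", "lat"])
        fac["facility_type"] = fac["facility_type"].astype(object)
        d = nearest_facility_distance(blocks, fac)
        assert d.empty or d.isna().all().all()


class TestProjectPoints:
    def test_planar_passthrough(self):
        blocks = lattice_blocks(2, 2, cell=1000.0)  # crs="planar"
        df = make_records([("a", 100.0, 200.0, "t", "OD-CONFIRMED", False)])
        pat = project_points(df, blocks)
        np.testing.assert_array_equal(pat.points, [[100.0, 200.0]])
        assert pat.crs == "planar"

    def test_n_preserved_and_roundtrip(self):
        # WGS84 block over Cincinnati-ish coordinates
        import pandas as pd
        from shapely.geometry import Polygon

        from spatclust.core import BlockGroupSet

        ring = [(-84.6, 39.0), (-84.4, 39.0), (-84.4, 39.2), (-84.6, 39.2)]
        blocks = BlockGroupSet(
            ids=["w"], geometries=[Polygon(ring)],
            data=pd.DataFrame({"adult_population": [100]},
                              index=pd.Index(["w"], name="block_id")),
            crs="EPSG:4326")
        lons = [-84.55, -84.45, -84.5]
        lats = [39.05, 39.15, 39.1]
        df = make_records([
            (f"r{i}", lon, lat, "t", "OD-CONFIRMED", False)
            for i, (lon, lat) in enumerate(zip(lons, lats))])
        pat = project_points(df, blocks)
        assert pat.n == 3
        assert pat.crs == "utm:16N"
        # projected points match a direct forward projection
        e, n = geographic_to_utm(np.array(lons), np.array(lats), 16)
        np.testing.assert_allclose(pat.points[:, 0], e, atol=1e-6)
        np.testing.assert_allclose(pat.points[:, 1], n, atol=1e-6)
        # area is in m^2 and plausible for ~17km x 22km
        assert 2.5e8 < pat.area < 5e8
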