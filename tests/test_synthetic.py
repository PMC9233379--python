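"""Synthetic city generator: determinism, contamination accounting,
planted-signal structure."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from spatclust.core import ConfigurationError
from spatclust.ingest import filter_incidents
from spatclust.synthetic import (ASSOCIATED_DISPOSITION, ContaminationSpec,
                                 CovariateEffects, SyntheticCityConfig,
                                 generate_block_lattice, generate_covariates,
                                 generate_facilities, generate_incidents,
                                 write_city)


def small_config(**kw):
    defaults = dict(n_rows=4, n_cols=5, cell_size_m=1000.0,
                    years=(2015, 2016), base_annual_rate=2.0, seed=7)
    defaults.update(kw)
    return SyntheticCityConfig(**defaults)


class TestLattice:
    def test_2x2_geometry(self):
        cfg = small_config(n_rows=2, n_cols=2)
        blocks = generate_block_lattice(cfg)
        assert len(blocks) == 4
        assert blocks.window.area == pytest.approx(4e6)

    def test_determinism(self):
        cfg = small_config()
        b1 = generate_block_lattice(cfg)
        b2 = generate_block_lattice(cfg)
        pd.testing.assert_frame_equal(b1.data, b2.data)
        assert all(g1.equals(g2)
                   for g1, g2 in zip(b1.geometries, b2.geometries))

    def test_study_scale_count(self):
        blocks = generate_block_lattice(small_config(n_rows=14, n_cols=20))
        assert len(blocks) == 280

    def test_invalid_dimensions(self):
        with pytest.raises(ConfigurationError):
            small_config(n_rows=0)
        with pytest.raises(ConfigurationError):
            small_config(n_rows=1, n_cols=2)  # fewer than 4 blocks

    def test_population_positive_and_skewed(self):
        blocks = generate_block_lattice(small_config(n_rows=14, n_cols=20))
        pop = blocks.data["adult_population"]
        assert (pop > 0).all()
        assert pop.median() == pytest.approx(980, rel=0.25)


class TestCovariates:
    def test_null_effects_identical_in_law(self):
        cfg = small_config(hot_blocks=frozenset({(1, 1), (1, 2)}))
        blocks = generate_block_lattice(cfg)
        cov0 = generate_covariates(blocks, cfg.hot_ids, seed=3,
                                   effects=CovariateEffects.null())
        cov_none = generate_covariates(blocks, set(), seed=3,
                                       effects=CovariateEffects.null())
        pd.testing.assert_frame_equal(cov0, cov_none)

    def test_default_effects_shift_medians(self):
        cfg = SyntheticCityConfig(
            n_rows=10, n_cols=10,
            hot_blocks=frozenset((r, c) for r in range(3, 6)
                                 for c in range(3, 6)),
            hot_multiplier=5.0, seed=1)
        blocks = generate_block_lattice(cfg)
        cov = generate_covariates(blocks, cfg.hot_ids, seed=1)
        hot = blocks.data["hot"]
        assert cov.loc[hot, "income"].median() < cov.loc[~hot, "income"].median()
        assert (cov.loc[hot, "crime_rate"].median()
                > cov.loc[~hot, "crime_rate"].median())
        assert (cov.loc[hot, "pct_bachelor"].median()
                < cov.loc[~hot, "pct_bachelor"].median())

    def test_seeded_repeatability(self):
        cfg = small_config()
        blocks = generate_block_lattice(cfg)
        c1 = generate_covariates(blocks, set(), seed=9)
        c2 = generate_covariates(blocks, set(), seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_unknown_hot_block_error(self):
        cfg = small_config()
        blocks = generate_block_lattice(cfg)
        with pytest.raises(ConfigurationError):
            generate_covariates(blocks, {"nope"}, seed=0)


class TestIncidents:
    def test_poisson_total_within_four_sd(self):
        cfg = SyntheticCityConfig(n_rows=8, n_cols=8, base_annual_rate=3.0,
                                  years=(2015, 2016, 2017), seed=5)
        blocks = generate_block_lattice(cfg)
        cov = generate_covariates(blocks, set(), seed=5)
        inc = generate_incidents(blocks, cov, cfg)
        mean = (blocks.data["adult_population"] / 1000.0 * 3.0 * 3).sum()
        assert abs(len(inc) - mean) <= 4 * np.sqrt(mean)

    def test_duplicates_are_byte_identical(self):
        cfg = small_config(
            contamination=ContaminationSpec(n_duplicates=3))
        blocks = generate_block_lattice(cfg)
        cov = generate_covariates(blocks, set(), seed=7)
        inc = generate_incidents(blocks, cov, cfg)
        dup_mask = inc.duplicated(keep="first")
        assert dup_mask.sum() == 3

    def test_contamination_accounting_exact(self, unit_square):
        spec = ContaminationSpec(n_duplicates=2, n_cancelled=3,
                                 n_missing_geocode=4, n_outside_area=5,
                                 n_unassociated=1)
        cfg = small_config(contamination=spec)
        blocks = generate_block_lattice(cfg)
        cov = generate_covariates(blocks, set(), seed=7)
        inc = generate_incidents(blocks, cov, cfg)
        _, tally = filter_incidents(inc, blocks.window,
                                    {ASSOCIATED_DISPOSITION})
        assert tally.duplicate == 2
        assert tally.cancelled_or_false_alarm == 3
        assert tally.missing_geocode == 4
        assert tally.outside_area == 5
        assert tally.unassociated_disposition == 1
        assert tally.retained == len(inc) - 15

    def test_points_inside_window_or_flagged_outside(self):
        spec = ContaminationSpec(n_outside_area=10)
        cfg = small_config(contamination=spec)
        blocks = generate_block_lattice(cfg)
        cov = generate_covariates(blocks, set(), seed=7)
        inc = generate_incidents(blocks, cov, cfg)
        window = blocks.window
        geo = inc.dropna(subset=["lon"])
        inside = geo.apply(
            lambda r: window.covers(Point(r["lon"], r["lat"])), axis=1)
        outside_ids = geo.loc[~inside, "record_id"]
        assert len(outside_ids) == 10
        assert outside_ids.str.startswith("C").all()
        # outside points stay within one window-width of the boundary
        xmin, ymin, xmax, ymax = window.bounds
        w, h = xmax - xmin, ymax - ymin
        for _, r in geo.loc[~inside].iterrows():
            assert xmin - w <= r["lon"] <= xmax + w
            assert ymin - h <= r["lat"] <= ymax + h

    def test_hot_multiplier_raises_counts(self):
        hot = frozenset((r, c) for r in range(1, 3) for c in range(1, 3))
        cfg = SyntheticCityConfig(n_rows=8, n_cols=8, base_annual_rate=2.0,
                                  years=tuple(range(2015, 2021)),
                                  hot_blocks=hot, hot_multiplier=8.0, seed=2)
        blocks = generate_block_lattice(cfg)
        cov = generate_covariates(blocks, cfg.hot_ids, seed=2)
        inc = generate_incidents(blocks, cov, cfg)
        # count incidents per block via coordinates
        from spatclust.ingest import assign_to_blocks

        counts = assign_to_blocks(inc, blocks)
        hot_mean = counts[list(cfg.hot_ids)].mean()
        cold_ids = [b for b in blocks.ids if b not in cfg.hot_ids]
        assert hot_mean > 3 * counts[cold_ids].mean()

    def test_empty_blocks_error(self):
        cfg = small_config()
        blocks = generate_block_lattice(cfg)
        empty = blocks
        empty_blocks = type(blocks)(
            ids=[], geometries=[],
            data=blocks.data.iloc[:0], crs=blocks.crs)
        with pytest.raises(ConfigurationError):
            generate_incidents(empty_blocks, None, cfg)


class TestFacilities:
    def test_zero_count_type_empty(self, unit_square):
        fac = generate_facilities(unit_square,
                                  {"hospital": 0, "otp": 2}, seed=1)
        assert (fac["facility_type"] == "hospital").sum() == 0
        assert (fac["facility_type"] == "otp").sum() == 2

    def test_partitions_into_requested_types(self, unit_square):
        fac = generate_facilities(
            unit_square, {"hospital": 3, "otp": 2, "bup": 4}, seed=1)
        assert fac["facility_type"].value_counts().to_dict() == {
            "bup": 4, "hospital": 3, "otp": 2}
        assert len(fac) == 9

    def test_seeded_determinism(self, unit_square):
        f1 = generate_facilities(unit_square, {"otp": 5}, seed=3)
        f2 = generate_facilities(unit_square, {"otp": 5}, seed=3)
        pd.testing.assert_frame_equal(f1, f2)


class TestWriteCity:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = small_config(
            hot_blocks=frozenset({(1, 1)}), hot_multiplier=3.0,
            contamination=ContaminationSpec(1, 1, 1, 1))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_city(cfg, d1)
        write_city(cfg, d2)
        for name in ("blocks.geojson", "covariates.csv", "incidents.csv",
                     "facilities.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_wgs84_bundle_loads_and_projects(self, tmp_path):
        from spatclust.geo import blocks_from_geojson

        cfg = small_config()
        write_city(cfg, tmp_path, wgs84=True)
        blocks = blocks_from_geojson(tmp_path / "blocks.geojson")
        assert blocks.crs == "EPSG:4326"
        b = blocks.window.bounds
        assert -90 < b[0] < -80 and 35 < b[1] < 42
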