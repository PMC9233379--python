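"""Synthetic city generator: a polygon lattice with spatially correlated
covariates, an inhomogeneous incident process with planted hot blocks,
facility locations, and controlled record contamination (duplicates,
cancelled calls, missing geocodes, out-of-area points) so that every
downstream stage — exclusion rules included — is exercisable offline.

All randomness flows from the single config seed through named
generators; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

from .core import CRS_PLANAR, CRS_WGS84, BlockGroupSet, ConfigurationError
from .geo import blocks_to_geojson
from .projection import utm_to_geographic

__all__ = [
    "ContaminationSpec",
    "CovariateEffects",
    "SyntheticCityConfig",
    "generate_block_lattice",
    "generate_covariates",
    "generate_incidents",
    "generate_facilities",
    "generate_city",
    "write_city",
]

ASSOCIATED_DISPOSITION = "OD-CONFIRMED"
UNASSOCIATED_DISPOSITION = "OTHER"

# Anchor for expressing the planar lattice in WGS84: the south-west corner
# of the lattice maps to this UTM position (zone 16N, mid-latitudes).
_ANCHOR_EASTING = 700_000.0
_ANCHOR_NORTHING = 4_320_000.0
_ANCHOR_ZONE = 16


@dataclass(frozen=True)
class ContaminationSpec:
    """How many contaminated records of each class to append."""

    n_duplicates: int = 0
    n_cancelled: int = 0
    n_missing_geocode: int = 0
    n_outside_area: int = 0
    n_unassociated: int = 0  # extension: records with a non-associated code

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class CovariateEffects:
    """Additive shifts applied to covariates of hot blocks (directions:
    hot areas get more males, more poverty, more crime, less education,
    less income)."""

    pct_male: float = 6.0
    pct_poverty: float = 15.0
    pct_bachelor: float = -15.0
    income: float = -9000.0
    crime_rate: float = 12.0

    @classmethod
    def null(cls) -> "CovariateEffects":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticCityConfig:
    n_rows: int = 14
    n_cols: int = 20
    cell_size_m: float = 1000.0
    years: tuple = (2015, 2016, 2017, 2018, 2019, 2020)
    base_annual_rate: float = 0.6  # incidents / 1,000 adults / year
    hot_blocks: frozenset = frozenset()  # {(row, col), ...}
    hot_multiplier: float = 1.0
    contamination: ContaminationSpec = ContaminationSpec()
    effects: CovariateEffects = CovariateEffects()
    pop_median: float = 980.0  # log-normal median of adult population
    pop_sigma: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("lattice dimensions must be positive")
        if self.n_rows * self.n_cols < 4:
            raise ConfigurationError("lattice must have at least 4 blocks")
        if self.cell_size_m <= 0:
            raise ConfigurationError("cell_size_m must be positive")
        if not self.years:
            raise ConfigurationError("years must be non-empty")
        if self.hot_multiplier < 1.0:
            raise ConfigurationError("hot_multiplier must be >= 1")
        for r, c in self.hot_blocks:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ConfigurationError(f"hot block {(r, c)} outside lattice")

    def block_id(self, row: int, col: int) -> str:
        return f"B{row:03d}{col:03d}"

    @property
    def hot_ids(self) -> set:
        return {self.block_id(r, c) for r, c in self.hot_blocks}


def _rng(config: SyntheticCityConfig, stream: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str hash is salted)
    key = zlib.crc32(stream.encode())
    ss = np.random.SeedSequence(config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def generate_block_lattice(config: SyntheticCityConfig) -> BlockGroupSet:
    """Rectangular lattice of n_rows x n_cols square blocks (planar metres)
    with log-normal adult populations."""
    rng = _rng(config, "population")
    s = config.cell_size_m
    ids, geoms = [], []
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            ids.append(config.block_id(r, c))
            geoms.append(box(c * s, r * s, (c + 1) * s, (r + 1) * s))
    pop = rng.lognormal(mean=np.log(config.pop_median),
                        sigma=config.pop_sigma, size=len(ids))
    data = pd.DataFrame(
        {
            "adult_population": np.round(pop).astype(int),
            "row": [r for r in range(config.n_rows) for _ in range(config.n_cols)],
            "col": list(range(config.n_cols)) * config.n_rows,
            "hot": [bid in config.hot_ids for bid in ids],
        },
        index=pd.Index(ids, name="block_id"),
    )
    return BlockGroupSet(ids=ids, geometries=geoms, data=data, crs=CRS_PLANAR)


def _correlated_field(rng, n_rows, n_cols, sigma=2.0):
    """Smooth unit-variance lattice field (Gaussian-filtered white noise)."""
    f = gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=sigma,
                        mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_covariates(blocks: BlockGroupSet, hot_blocks, seed: int,
                        effects: CovariateEffects = CovariateEffects()) -> pd.DataFrame:
    """Spatially correlated sociodemographic covariates, shifted on hot
    blocks in the directions observed for real hot spots."""
    hot_ids = set(hot_blocks)
    unknown = hot_ids - set(blocks.ids)
    if unknown:
        raise ConfigurationError(f"unknown hot block ids: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    n_rows = int(blocks.data["row"].max()) + 1
    n_cols = int(blocks.data["col"].max()) + 1
    rr = blocks.data["row"].to_numpy()
    cc = blocks.data["col"].to_numpy()

    def fld():
        return _correlated_field(rng, n_rows, n_cols)[rr, cc]

    hot = np.array([b in hot_ids for b in blocks.ids])
    cov = pd.DataFrame(index=blocks.data.index)
    cov["pct_male"] = np.clip(49 + 4 * fld() + effects.pct_male * hot, 25, 75)
    cov["pct_poverty"] = np.clip(22 + 10 * fld() + effects.pct_poverty * hot, 0, 95)
    cov["pct_bachelor"] = np.clip(29 + 12 * fld() + effects.pct_bachelor * hot, 1, 95)
    cov["income"] = np.clip(24_500 + 8_000 * fld() + effects.income * hot,
                            4_000, None)
    cov["crime_rate"] = np.clip(8 + 5 * fld() + effects.crime_rate * hot, 0, None)
    return cov


def generate_incidents(blocks: BlockGroupSet, covariates: pd.DataFrame,
                       config: SyntheticCityConfig) -> pd.DataFrame:
    """Incident stream: per block and year a Poisson count with mean
    adult_population/1000 * base_annual_rate * (hot_multiplier on hot
    blocks), points uniform within the block, contamination appended.

    Contaminated records are constructed to be excluded under exactly one
    rule each (in the ingest module's fixed order); duplicates are exact
    copies of earlier clean records.
    """
    if len(blocks) == 0:
        raise ConfigurationError("empty block set")
    rng = _rng(config, "incidents")
    rows = []
    rid = 0
    for bid, geom in zip(blocks.ids, blocks.geometries):
        pop = blocks.data.at[bid, "adult_population"]
        hot = bid in config.hot_ids
        mean = pop / 1000.0 * config.base_annual_rate
        if hot:
            mean *= config.hot_multiplier
        xmin, ymin, xmax, ymax = geom.bounds
        for year in config.years:
            k = rng.poisson(mean)
            for _ in range(k):
                # blocks are rectangles; uniform in bounds is uniform in block
                x = rng.uniform(xmin, xmax)
                y = rng.uniform(ymin, ymax)
                day = rng.integers(0, 365)
                rows.append((f"R{rid:06d}", x, y,
                             f"{year}-{1 + day // 31:02d}-{1 + day % 28:02d}",
                             ASSOCIATED_DISPOSITION, False))
                rid += 1
    clean = pd.DataFrame(rows, columns=["record_id", "lon", "lat", "timestamp",
                                        "disposition_code", "cancelled_flag"])

    spec = config.contamination
    crng = _rng(config, "contamination")
    window = blocks.window
    xmin, ymin, xmax, ymax = window.bounds
    width = xmax - xmin
    height = ymax - ymin
    extra = []

    if spec.n_duplicates > 0:
        if clean.empty:
            raise ConfigurationError("cannot duplicate records: no clean records")
        picks = crng.choice(len(clean), size=spec.n_duplicates, replace=True)
        for p in picks:
            extra.append(tuple(clean.iloc[int(p)]))
    for _ in range(spec.n_cancelled):
        extra.append((f"C{rid:06d}", crng.uniform(xmin, xmax),
                      crng.uniform(ymin, ymax), "2017-06-15",
                      ASSOCIATED_DISPOSITION, True))
        rid += 1
    for _ in range(spec.n_missing_geocode):
        extra.append((f"C{rid:06d}", np.nan, np.nan, "2017-06-15",
                      ASSOCIATED_DISPOSITION, False))
        rid += 1
    for _ in range(spec.n_outside_area):
        # within one window-width of the boundary, strictly outside
        side = crng.integers(0, 4)
        off = crng.uniform(0.01, 1.0)
        if side == 0:
            x, y = xmin - off * width, crng.uniform(ymin, ymax)
        elif side == 1:
            x, y = xmax + off * width, crng.uniform(ymin, ymax)
        elif side == 2:
            x, y = crng.uniform(xmin, xmax), ymin - off * height
        else:
            x, y = crng.uniform(xmin, xmax), ymax + off * height
        extra.append((f"C{rid:06d}", x, y, "2017-06-15",
                      ASSOCIATED_DISPOSITION, False))
        rid += 1
    for _ in range(spec.n_unassociated):
        extra.append((f"C{rid:06d}", crng.uniform(xmin, xmax),
                      crng.uniform(ymin, ymax), "2017-06-15",
                      UNASSOCIATED_DISPOSITION, False))
        rid += 1

    if extra:
        extra_df = pd.DataFrame(extra, columns=clean.columns)
        out = pd.concat([clean, extra_df], ignore_index=True)
    else:
        out = clean
    return out


def generate_facilities(window, counts_per_type: dict, seed: int,
                        offset_outside: float = 0.0) -> pd.DataFrame:
    """Uniform facility points per type inside the window (or within
    ``offset_outside`` metres beyond its bounds when requested)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(13,)))
    xmin, ymin, xmax, ymax = window.bounds
    rows = []
    fid = 0
    for ftype in sorted(counts_per_type):
        count = counts_per_type[ftype]
        if count < 0:
            raise ConfigurationError(f"negative count for {ftype!r}")
        for _ in range(count):
            x = rng.uniform(xmin - offset_outside, xmax + offset_outside)
            y = rng.uniform(ymin - offset_outside, ymax + offset_outside)
            rows.append((f"F{fid:04d}", ftype, x, y))
            fid += 1
    return pd.DataFrame(rows, columns=["facility_id", "facility_type",
                                       "lon", "lat"])


def generate_city(config: SyntheticCityConfig,
                  facility_counts: dict | None = None):
    """Generate the full synthetic bundle (planar coordinates).

    Returns (blocks, covariates, incidents, facilities); covariates are
    merged into ``blocks.data``.
    """
    blocks = generate_block_lattice(config)
    cov = generate_covariates(blocks, config.hot_ids, config.seed,
                              effects=config.effects)
    blocks.data = blocks.data.join(cov)
    incidents = generate_incidents(blocks, cov, config)
    if facility_counts is None:
        facility_counts = {"hospital": 4, "otp": 3, "buprenorphine": 8}
    facilities = generate_facilities(blocks.window, facility_counts,
                                     config.seed)
    return blocks, cov, incidents, facilities


def _to_wgs84_blocks(blocks: BlockGroupSet) -> BlockGroupSet:
    """Re-express a planar lattice in WGS84 via the anchor UTM frame."""
    geoms = []
    for g in blocks.geometries:
        ring = np.asarray(g.exterior.coords)
        lon, lat = utm_to_geographic(ring[:, 0] + _ANCHOR_EASTING,
                                     ring[:, 1] + _ANCHOR_NORTHING,
                                     _ANCHOR_ZONE)
        geoms.append(Polygon(np.column_stack([lon, lat])))
    return BlockGroupSet(ids=list(blocks.ids), geometries=geoms,
                         data=blocks.data.copy(), crs=CRS_WGS84)


def write_city(config: SyntheticCityConfig, outdir, wgs84: bool = False,
               facility_counts: dict | None = None) -> dict:
    """Generate and write the bundle: blocks.geojson, covariates.csv,
    incidents.csv, facilities.csv. Returns the written paths.

    With ``wgs84=True`` all coordinates are re-expressed as WGS84 lon/lat
    (anchored in UTM zone 16N); otherwise they stay planar metres.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blocks, cov, incidents, facilities = generate_city(config, facility_counts)
    if wgs84:
        geo = np.flatnonzero(incidents["lon"].notna().to_numpy())
        lon = incidents["lon"].to_numpy(dtype=float)
        lat = incidents["lat"].to_numpy(dtype=float)
        glon, glat = utm_to_geographic(lon[geo] + _ANCHOR_EASTING,
                                       lat[geo] + _ANCHOR_NORTHING,
                                       _ANCHOR_ZONE)
        lon[geo], lat[geo] = glon, glat
        incidents = incidents.assign(lon=lon, lat=lat)
        flon, flat_ = utm_to_geographic(
            facilities["lon"].to_numpy() + _ANCHOR_EASTING,
            facilities["lat"].to_numpy() + _ANCHOR_NORTHING, _ANCHOR_ZONE)
        facilities = facilities.assign(lon=flon, lat=flat_)
        blocks = _to_wgs84_blocks(blocks)
    paths = {
        "blocks": outdir / "blocks.geojson",
        "covariates": outdir / "covariates.csv",
        "incidents": outdir / "incidents.csv",
        "facilities": outdir / "facilities.csv",
    }
    blocks_to_geojson(blocks, paths["blocks"])
    cov.to_csv(paths["covariates"])
    incidents.to_csv(paths["incidents"], index=False)
    facilities.to_csv(paths["facilities"], index=False)
    return {k: str(v) for k, v in paths.items()}
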