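"""Incident cleaning, areal assignment, rate construction and projection.

Exclusion rules are applied in a fixed order so the tally is a partition
of the input: missing geocode -> outside study area -> unassociated
disposition -> cancelled/false alarm -> duplicate. A duplicate is a
record with a previously seen record_id, or a previously seen
(lon, lat, timestamp, disposition_code) quadruple; the first occurrence
is kept.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .core import (
    CRS_PLANAR,
    CRS_WGS84,
    TEN_MILES_M,
    BlockGroupSet,
    ConfigurationError,
    ExclusionTally,
    PointPattern,
)
from .projection import geographic_to_utm, utm_zone

__all__ = [
    "filter_incidents",
    "assign_to_blocks",
    "compute_rates",
    "nearest_facility_distance",
    "project_points",
]


def filter_incidents(records: pd.DataFrame, window,
                     associated_dispositions) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the exclusion rules; return retained records and the tally.

    Each input record is counted under exactly one reason (fixed order
    above) or retained. Input order is preserved among retained records.
    """
    associated = set(associated_dispositions)
    if not associated:
        raise ConfigurationError("associated disposition set is empty")
    df = records.reset_index(drop=True)

    tally = ExclusionTally()
    has_geo = df["lon"].notna() & df["lat"].notna()
    tally.missing_geocode = int((~has_geo).sum())

    inside = np.zeros(len(df), dtype=bool)
    idx_geo = np.flatnonzero(has_geo.to_numpy())
    if idx_geo.size:
        pts = shapely.points(
            np.column_stack([
                df["lon"].to_numpy()[idx_geo],
                df["lat"].to_numpy()[idx_geo],
            ])
        )
        inside[idx_geo] = shapely.covers(window, pts)
    stage2 = has_geo.to_numpy() & ~inside
    tally.outside_area = int(stage2.sum())
    alive = has_geo.to_numpy() & inside

    assoc = df["disposition_code"].isin(associated).to_numpy()
    tally.unassociated_disposition = int((alive & ~assoc).sum())
    alive &= assoc

    cancelled = df["cancelled_flag"].astype(bool).to_numpy()
    tally.cancelled_or_false_alarm = int((alive & cancelled).sum())
    alive &= ~cancelled

    # duplicates among survivors, first occurrence kept
    sub = df.loc[alive]
    dup_id = sub["record_id"].duplicated(keep="first")
    dup_key = sub.duplicated(
        subset=["lon", "lat", "timestamp", "disposition_code"], keep="first"
    )
    dup = (dup_id | dup_key).to_numpy()
    tally.duplicate = int(dup.sum())
    retained = sub.loc[~dup].copy()
    tally.retained = len(retained)

    assert tally.total == len(df), "exclusion tally failed to partition input"
    return retained, tally


def assign_to_blocks(records: pd.DataFrame, blocks: BlockGroupSet) -> pd.Series:
    """Point-in-polygon counts per block for already-filtered records.

    Boundary points are assigned to exactly one block: the covering block
    with the lowest block_id. A record covered by no block is a hard
    error — the containment filter should have removed it.
    """
    counts = pd.Series(0, index=pd.Index(blocks.ids, name="block_id"), dtype=int)
    if records.empty:
        return counts
    pts = shapely.points(
        np.column_stack([records["lon"].to_numpy(), records["lat"].to_numpy()])
    )
    tree = STRtree(blocks.geometries)
    hit_pt, hit_blk = tree.query(pts, predicate="covered_by")
    assignments: dict[int, int] = {}
    for p, b in zip(hit_pt, hit_blk):
        p, b = int(p), int(b)
        if p not in assignments or blocks.ids[b] < blocks.ids[assignments[p]]:
            assignments[p] = b
    if len(assignments) != len(records):
        missing = set(range(len(records))) - set(assignments)
        rid = records.iloc[sorted(missing)[0]]["record_id"]
        raise ValueError(
            f"record {rid!r} lies outside every block; filter_incidents "
            "should have excluded it"
        )
    for b in assignments.values():
        counts.iloc[b] += 1
    return counts


def compute_rates(counts: pd.Series, blocks: BlockGroupSet,
                  n_years: int) -> pd.DataFrame:
    """Average annual incidents per 1,000 adult population per block.

    rate_b = (count_b / n_years) / adult_population_b * 1000. Blocks with
    zero adult population are excluded from the result (reported via the
    ``excluded_zero_population`` attribute on the returned frame).
    """
    if n_years <= 0:
        raise ValueError(f"n_years must be positive, got {n_years}")
    pop = blocks.data["adult_population"].astype(float)
    if (pop < 0).any():
        raise ValueError("negative adult_population")
    counts = counts.reindex(blocks.ids).fillna(0).astype(float)
    ok = pop > 0
    rate = (counts[ok] / n_years) / pop[ok] * 1000.0
    out = pd.DataFrame({
        "incident_count": counts[ok].astype(int),
        "incident_rate": rate,
    })
    out.index.name = "block_id"
    out.attrs["excluded_zero_population"] = [b for b in blocks.ids if not ok[b]]
    return out


def nearest_facility_distance(blocks: BlockGroupSet,
                              facilities: pd.DataFrame) -> pd.DataFrame:
    """Centroid-to-nearest-facility distance per block and facility type,
    in 10-mile units (Euclidean, projected coordinates).

    Facility coordinates must be in the same planar frame as the blocks
    (columns ``x``/``y``, or ``lon``/``lat`` interpreted as planar when
    the blocks are planar). Types with no facilities yield NaN columns
    and a warning.
    """
    xcol, ycol = ("x", "y") if "x" in facilities.columns else ("lon", "lat")
    cents = np.array([[g.centroid.x, g.centroid.y] for g in blocks.geometries])
    out = pd.DataFrame(index=pd.Index(blocks.ids, name="block_id"))
    types = sorted(facilities["facility_type"].unique())
    for ftype in types:
        sub = facilities.loc[facilities["facility_type"] == ftype]
        col = f"dist_{ftype}"
        if sub.empty:
            warnings.warn(f"no facilities of type {ftype!r}; distance undefined")
            out[col] = np.nan
            continue
        fxy = sub[[xcol, ycol]].to_numpy(dtype=float)
        d = np.sqrt(
            ((cents[:, None, :] - fxy[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
        out[col] = d / TEN_MILES_M
    return out


def project_points(records: pd.DataFrame, blocks: BlockGroupSet) -> PointPattern:
    """Project retained incident points and the study window to UTM.

    When the blocks are already planar (synthetic or pre-projected data)
    the coordinates pass through unchanged. Otherwise the UTM zone of the
    window centroid is used; windows spanning more than two zones trigger
    a warning, not an error.
    """
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    if blocks.crs != CRS_WGS84:
        window = blocks.window
        return PointPattern(points=np.column_stack([lon, lat]),
                            window=window, crs=CRS_PLANAR)

    window = blocks.window
    c = window.centroid
    zone = utm_zone(c.x, c.y)
    xmin, _, xmax, _ = window.bounds
    if utm_zone(xmax, c.y) - utm_zone(xmin, c.y) > 2:
        warnings.warn(
            "window spans more than two UTM zones; using the centroid zone"
        )
    northern = c.y >= 0
    ex, ny = geographic_to_utm(lon, lat, zone, northern=northern)

    ring = np.asarray(window.exterior.coords)
    rx, ry = geographic_to_utm(ring[:, 0], ring[:, 1], zone, northern=northern)
    from shapely.geometry import Polygon

    win_utm = Polygon(np.column_stack([rx, ry]))
    return PointPattern(points=np.column_stack([ex, ny]), window=win_utm,
                        crs=f"utm:{zone}{'N' if northern else 'S'}")
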