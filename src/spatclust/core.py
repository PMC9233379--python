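"""Shared domain types for the areal clustering pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

#: 10 miles in metres — facility distances are reported in this unit.
TEN_MILES_M = 16_093.4

#: CRS tags used throughout. "EPSG:4326" is WGS84 lon/lat; "planar" means
#: projected metres (UTM easting/northing or synthetic local coordinates).
CRS_WGS84 = "EPSG:4326"
CRS_PLANAR = "planar"


class ConfigurationError(ValueError):
    """Raised when a user-supplied configuration violates a contract."""


@dataclass
class BlockGroupSet:
    """Areal units: one polygon per block group plus attached attributes.

    ``data`` is indexed by ``block_id`` (aligned with ``geometries``) and
    always carries an ``adult_population`` column; covariate and
    facility-distance columns are added by later stages.
    """

    ids: list
    geometries: list
    data: pd.DataFrame
    crs: str = CRS_PLANAR

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.geometries):
            raise ValueError("ids and geometries length mismatch")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("block ids must be unique")
        if not self.data.index.equals(pd.Index(self.ids)):
            raise ValueError("data must be indexed by block ids, in order")
        for bid, geom in zip(self.ids, self.geometries):
            if not isinstance(geom, BaseGeometry) or geom.is_empty:
                raise ValueError(f"block {bid!r}: empty or invalid geometry")
            if not geom.is_valid:
                raise ValueError(f"block {bid!r}: invalid polygon geometry")

    def __len__(self) -> int:
        return len(self.ids)

    @cached_property
    def window(self) -> Polygon:
        """Union of all block polygons (the study area)."""
        return unary_union(self.geometries)

    def geometry_of(self, block_id) -> BaseGeometry:
        return self.geometries[self.ids.index(block_id)]


@dataclass
class PointPattern:
    """A planar point set with its observation window.

    Coordinates must be in projected metres; ``window`` is the study-area
    polygon in the same frame.
    """

    points: np.ndarray
    window: Polygon
    crs: str = CRS_PLANAR

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.window.area <= 0:
            raise ValueError("window area must be positive")

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    @property
    def area(self) -> float:
        return float(self.window.area)

    @property
    def intensity(self) -> float:
        """Estimated intensity N / A."""
        return self.n / self.area


# Column conventions for tabular record sets (plain DataFrames, pandas
# idiom — no wrapper class needed):
INCIDENT_COLUMNS = [
    "record_id",
    "lon",
    "lat",
    "timestamp",
    "disposition_code",
    "cancelled_flag",
]

FACILITY_COLUMNS = ["facility_id", "facility_type", "lon", "lat"]


@dataclass
class ExclusionTally:
    """Partition of an incident set by the fixed-order exclusion rules."""

    missing_geocode: int = 0
    outside_area: int = 0
    unassociated_disposition: int = 0
    cancelled_or_false_alarm: int = 0
    duplicate: int = 0
    retained: int = 0

    REASONS = (
        "missing_geocode",
        "outside_area",
        "unassociated_disposition",
        "cancelled_or_false_alarm",
        "duplicate",
    )

    @property
    def excluded(self) -> int:
        return sum(getattr(self, r) for r in self.REASONS)

    @property
    def total(self) -> int:
        return self.excluded + self.retained

    def as_dict(self) -> dict:
        d = {r: getattr(self, r) for r in self.REASONS}
        d["retained"] = self.retained
        return d
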