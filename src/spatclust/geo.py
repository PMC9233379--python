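"""GeoJSON reading/writing and small geometry helpers (shapely-backed)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .core import CRS_WGS84, BlockGroupSet


def blocks_to_geojson(blocks: BlockGroupSet, path) -> None:
    """Write a BlockGroupSet as a GeoJSON FeatureCollection.

    Attribute columns become feature properties; ``block_id`` is both the
    feature id and a property.
    """
    features = []
    for bid, geom in zip(blocks.ids, blocks.geometries):
        props = {"block_id": bid}
        row = blocks.data.loc[bid]
        for col, val in row.items():
            if isinstance(val, (np.floating, float)):
                val = float(val)
            elif isinstance(val, (np.integer, int)):
                val = int(val)
            elif isinstance(val, np.bool_):
                val = bool(val)
            props[col] = val
        features.append(
            {
                "type": "Feature",
                "id": bid,
                "properties": props,
                "geometry": mapping(geom),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs_tag": blocks.crs,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def blocks_from_geojson(path, crs: str | None = None) -> BlockGroupSet:
    """Read a FeatureCollection of polygons into a BlockGroupSet.

    Features must carry a ``block_id`` property (or an ``id``); all other
    properties become attribute columns.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    ids, geoms, rows = [], [], []
    for feat in doc["features"]:
        props = dict(feat.get("properties") or {})
        bid = props.pop("block_id", feat.get("id"))
        if bid is None:
            raise ValueError(f"{path}: feature without block_id")
        ids.append(bid)
        geoms.append(shape(feat["geometry"]))
        rows.append(props)
    data = pd.DataFrame(rows, index=pd.Index(ids, name="block_id"))
    tag = crs or doc.get("crs_tag", CRS_WGS84)
    return BlockGroupSet(ids=ids, geometries=geoms, data=data, crs=tag)


def polygon_to_geojson(geom, path, crs: str = CRS_WGS84) -> None:
    doc = {"type": "Feature", "crs_tag": crs, "properties": {}, "geometry": mapping(geom)}
    Path(path).write_text(json.dumps(doc))


def polygon_from_geojson(path):
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "Feature":
        return shape(doc["geometry"]), doc.get("crs_tag", CRS_WGS84)
    if doc.get("type") == "FeatureCollection":
        from shapely.ops import unary_union

        return (
            unary_union([shape(f["geometry"]) for f in doc["features"]]),
            doc.get("crs_tag", CRS_WGS84),
        )
    return shape(doc), CRS_WGS84


def as_rectangle(polygon) -> tuple[float, float, float, float] | None:
    """Return (xmin, ymin, xmax, ymax) if the polygon is an axis-aligned
    rectangle (to floating tolerance), else None.

    Rectangular windows get closed-form fast paths in the point-pattern
    kernels.
    """
    if not isinstance(polygon, Polygon) or polygon.interiors:
        return None
    xmin, ymin, xmax, ymax = polygon.bounds
    rect_area = (xmax - xmin) * (ymax - ymin)
    if rect_area <= 0:
        return None
    if abs(polygon.area - rect_area) > 1e-9 * rect_area:
        return None
    return xmin, ymin, xmax, ymax


def exterior_coords(polygon) -> np.ndarray:
    """Exterior ring vertices as an (m, 2) array (closed ring)."""
    if not isinstance(polygon, Polygon):
        raise ValueError("expected a simple Polygon window")
    if polygon.interiors:
        raise ValueError("windows with holes are not supported")
    return np.asarray(polygon.exterior.coords, dtype=float)
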