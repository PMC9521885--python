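"""Optional point-in-polygon matching for complaints with only lat/lon.

Polygons come from a GeoJSON FeatureCollection; each feature needs an ``id``
(or an ``id`` property) naming the unit or zip it represents. Coordinates
are WGS84 lon/lat. A point on a shared boundary is assigned to the first
containing feature in file order.
"""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import Point, shape
from shapely.prepared import prep


def load_polygons(path: str | Path) -> list[tuple[str, object]]:
    """Read a FeatureCollection into an ordered [(id, geometry), ...] list."""
    gj = json.loads(Path(path).read_text())
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = []
    for feat in gj["features"]:
        fid = feat.get("id") or feat.get("properties", {}).get("id")
        if fid is None:
            raise ValueError("every polygon feature needs an 'id'")
        out.append((str(fid), shape(feat["geometry"])))
    return out


def assign_points(lons, lats, polygons: list[tuple[str, object]]) -> list[str | None]:
    """Assign each lon/lat point to the first containing polygon's id."""
    prepared = [(fid, prep(geom)) for fid, geom in polygons]
    out: list[str | None] = []
    for lon, lat in zip(lons, lats):
        p = Point(float(lon), float(lat))
        hit = next((fid for fid, g in prepared if g.intersects(p)), None)
        out.append(hit)
    return out
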