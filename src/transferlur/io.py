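"""File formats: readings CSV, segments/sites GeoJSON, aggregates CSV.

GeoJSON geometries are stored in WGS84 lon/lat (the format's convention)
and projected to a local metric plane on read via
:class:`transferlur.geo.LocalProjection`; all planar processing
(snapping, buffering, site matching) happens in that projection.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape
from shapely.ops import transform as shp_transform

from .geo import LocalProjection

READINGS_COLUMNS = ["reading_id", "time", "lon", "lat", "pollutant", "value"]
AGGREGATE_COLUMNS = ["segment_id", "pollutant", "value", "n_drive_pass", "n_points"]


def read_readings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in READINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"readings CSV {path} missing columns: {missing}")
    df["time"] = pd.to_datetime(df["time"], utc=True)
    return df


def write_readings_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in READINGS_COLUMNS
                                          if c in df.columns])


def read_geojson_features(path) -> list[tuple[object, dict]]:
    """(shapely geometry in lon/lat, properties) per GeoJSON feature."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    return [(shape(f["geometry"]), f.get("properties") or {})
            for f in gj["features"]]


def write_geojson_features(rows, path) -> None:
    """Write (geometry, properties) pairs as a FeatureCollection."""
    features = [{"type": "Feature", "geometry": mapping(geom),
                 "properties": props} for geom, props in rows]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _auto_projection(geoms) -> LocalProjection:
    lons, lats = [], []
    for g in geoms:
        c = g.centroid
        lons.append(c.x)
        lats.append(c.y)
    return LocalProjection(float(np.mean(lons)), float(np.mean(lats)))


def read_segments_geojson(path, projection: LocalProjection | None = None
                          ) -> tuple[pd.DataFrame, LocalProjection]:
    """Road segments as a frame with planar-metric geometries.

    Returns (frame with segment_id/city_id/geometry/length, projection);
    the projection defaults to one centred on the layer and is returned so
    readings can be projected consistently.
    """
    rows = read_geojson_features(path)
    if projection is None:
        projection = _auto_projection([g for g, _ in rows])

    def proj(geom):
        return shp_transform(lambda x, y: projection.to_xy(x, y), geom)

    recs = []
    for geom, props in rows:
        if "segment_id" not in props:
            raise ValueError(f"segment feature in {path} lacks 'segment_id'")
        g = proj(geom)
        recs.append({"segment_id": props["segment_id"],
                     "city_id": props.get("city_id", ""),
                     "geometry": g, "length": g.length})
    df = pd.DataFrame(recs)
    if df["segment_id"].duplicated().any():
        dupes = df.loc[df["segment_id"].duplicated(), "segment_id"].tolist()
        raise ValueError(f"duplicate segment_ids in {path}: {dupes[:5]}")
    return df, projection


def write_segments_geojson(segments_xy: pd.DataFrame, path,
                           projection: LocalProjection) -> None:
    """Write metric-plane segment geometries back to lon/lat GeoJSON."""
    rows = []
    for rec in segments_xy.itertuples(index=False):
        geom = shp_transform(lambda x, y: projection.to_lonlat(x, y), rec.geometry)
        rows.append((geom, {"segment_id": rec.segment_id,
                            "city_id": getattr(rec, "city_id", "")}))
    write_geojson_features(rows, path)


def project_readings(readings: pd.DataFrame,
                     projection: LocalProjection) -> pd.DataFrame:
    """Add planar x/y columns (meters) to lon/lat readings."""
    out = readings.copy()
    out["x"], out["y"] = projection.to_xy(out["lon"].to_numpy(),
                                          out["lat"].to_numpy())
    return out


def read_validation_csv(path, projection: LocalProjection) -> pd.DataFrame:
    """Fixed-site records (site_id, lon, lat, value) with metric point geometry."""
    df = pd.read_csv(path)
    for c in ("site_id", "lon", "lat", "value"):
        if c not in df.columns:
            raise ValueError(f"validation CSV {path} missing column {c!r}")
    x, y = projection.to_xy(df["lon"].to_numpy(), df["lat"].to_numpy())
    df["geometry"] = [Point(a, b) for a, b in zip(x, y)]
    return df


def read_reference_csv(path) -> pd.Series:
    """Hourly reference-site series from a CSV with columns time,value."""
    df = pd.read_csv(path)
    s = pd.Series(df["value"].to_numpy(dtype=float),
                  index=pd.to_datetime(df["time"], utc=True))
    return s


def write_aggregates_csv(agg: pd.DataFrame, path) -> None:
    agg.to_csv(path, index=False, columns=AGGREGATE_COLUMNS,
               float_format="%.17g")


def read_aggregates_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def grid_segments_xy(n_segments: int, city_id: str, spacing_m: float = 120.0,
                     seg_len_m: float = 50.0) -> pd.DataFrame:
    """Lay ~50 m segments on a square grid in the metric plane (for synthesis)."""
    cols = int(np.ceil(np.sqrt(n_segments)))
    half = cols * spacing_m / 2.0
    recs = []
    for i in range(n_segments):
        r, c = divmod(i, cols)
        x0, y0 = c * spacing_m - half, r * spacing_m - half
        recs.append({"segment_id": f"{city_id}_{i:05d}", "city_id": city_id,
                     "geometry": LineString([(x0, y0), (x0 + seg_len_m, y0)]),
                     "length": seg_len_m})
    return pd.DataFrame(recs)
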