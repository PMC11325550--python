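"""GIS buffer features per road segment, computed identically for all cities.

Three predictor groups, mirroring the harmonised land-use / road-network /
population inputs a multi-city LUR study uses:

* ``buffer_area_features`` — intersected area (m2) of each land-use class
  within circular buffers of 100/300/500/1000/5000 m around the segment
  midpoint;
* ``traffic_features``     — intensity on the nearest (major) road, plus
  per-buffer (25/50/100/300/500/1000 m) summed road length and
  length-weighted traffic-intensity sums, each for all/major roads and
  total/heavy-duty intensity;
* ``population_features``  — area-weighted population within each buffer.

All layers must share one planar metric CRS. Buffers are centred on the
segment midpoint. The assembled table has an identical, deterministic
column order for every city — a hard requirement of covariance alignment.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

#: the nine harmonised land-use classes
LAND_USE_CLASSES = ("agricultural", "airport", "industry", "natural", "port",
                    "residential", "transportation", "urban_green", "water")

AREA_BUFFERS_M = (100, 300, 500, 1000, 5000)
TRAFFIC_BUFFERS_M = (25, 50, 100, 300, 500, 1000)

#: circular-buffer discretisation; area error is O(1e-5) relative
_BUFFER_QUAD_SEGS = 64


def _midpoints(segments: pd.DataFrame):
    return [g.interpolate(0.5, normalized=True) for g in segments["geometry"]]


def buffer_area_features(segments: pd.DataFrame, landuse: pd.DataFrame,
                         classes=LAND_USE_CLASSES,
                         buffers_m=AREA_BUFFERS_M) -> pd.DataFrame:
    """Per-class intersected polygon area within each midpoint buffer.

    ``landuse`` carries shapely polygon geometries and a ``class`` column;
    an unknown class label raises.
    """
    unknown = set(landuse["class"]) - set(classes)
    if unknown:
        raise ValueError(f"unknown land-use classes: {sorted(unknown)}")
    mids = _midpoints(segments)
    cols = {}
    by_class = {c: landuse.loc[landuse["class"] == c, "geometry"].tolist()
                for c in classes}
    trees = {c: STRtree(geoms) if geoms else None for c, geoms in by_class.items()}
    for cls in classes:
        tree = trees[cls]
        for r in buffers_m:
            vals = np.zeros(len(mids))
            if tree is not None:
                for i, m in enumerate(mids):
                    buf = m.buffer(r, quad_segs=_BUFFER_QUAD_SEGS)
                    for j in tree.query(buf):
                        vals[i] += buf.intersection(tree.geometries[j]).area
            cols[f"{cls}_{r}"] = vals
    return pd.DataFrame(cols, index=segments["segment_id"].to_numpy())


def _nearest_attr(mids, roads: pd.DataFrame, attr: str) -> np.ndarray:
    """Attribute of the nearest road per midpoint (0 with a warning if empty)."""
    if len(roads) == 0:
        log.warning("no roads available for nearest-road feature %s; using 0", attr)
        return np.zeros(len(mids))
    tree = STRtree(list(roads["geometry"]))
    vals = roads[attr].to_numpy(dtype=float)
    out = np.empty(len(mids))
    for i, m in enumerate(mids):
        j = tree.nearest(m)
        out[i] = vals[j]
    return out


def traffic_features(segments: pd.DataFrame, roads: pd.DataFrame,
                     buffers_m=TRAFFIC_BUFFERS_M) -> pd.DataFrame:
    """Nearest-road intensities and per-buffer road-length / intensity sums.

    ``roads`` carries LineString geometries with columns ``intensity``
    (vehicles/day), ``hd_intensity`` (heavy-duty vehicles/day) and a boolean
    ``major`` flag. In-buffer intensity features are length-weighted sums
    (intensity x road length inside the buffer, veh*m/day).
    """
    for col in ("intensity", "hd_intensity", "major"):
        if col not in roads.columns:
            raise ValueError(f"road network missing column {col!r}")
    mids = _midpoints(segments)
    major = roads[roads["major"].astype(bool)]
    if len(major) == 0:
        log.warning("road network contains no major roads; "
                    "nearest-major features set to 0")

    cols = {
        "traffic_nearest": _nearest_attr(mids, roads, "intensity"),
        "traffic_nearest_major": _nearest_attr(mids, major, "intensity"),
        "hd_traffic_nearest": _nearest_attr(mids, roads, "hd_intensity"),
        "hd_traffic_nearest_major": _nearest_attr(mids, major, "hd_intensity"),
    }

    def in_buffer(sub: pd.DataFrame, suffix: str):
        tree = STRtree(list(sub["geometry"])) if len(sub) else None
        inten = sub["intensity"].to_numpy(dtype=float) if len(sub) else None
        hd = sub["hd_intensity"].to_numpy(dtype=float) if len(sub) else None
        for r in buffers_m:
            length = np.zeros(len(mids))
            wsum = np.zeros(len(mids))
            hdsum = np.zeros(len(mids))
            if tree is not None:
                for i, m in enumerate(mids):
                    buf = m.buffer(r, quad_segs=_BUFFER_QUAD_SEGS)
                    for j in tree.query(buf):
                        seg_len = buf.intersection(tree.geometries[j]).length
                        length[i] += seg_len
                        wsum[i] += inten[j] * seg_len
                        hdsum[i] += hd[j] * seg_len
            cols[f"roadlength{suffix}_{r}"] = length
            cols[f"traffic{suffix}_{r}"] = wsum
            cols[f"hd_traffic{suffix}_{r}"] = hdsum

    in_buffer(roads, "")
    in_buffer(major, "_major")
    return pd.DataFrame(cols, index=segments["segment_id"].to_numpy())


def population_features(segments: pd.DataFrame, population: pd.DataFrame,
                        buffers_m=AREA_BUFFERS_M) -> pd.DataFrame:
    """Area-weighted population sum within each midpoint buffer.

    ``population`` carries polygon cells with a ``population`` count; a cell
    partially covered by the buffer contributes proportionally to the
    covered fraction of its area.
    """
    mids = _midpoints(segments)
    cols = {}
    geoms = list(population["geometry"])
    counts = population["population"].to_numpy(dtype=float) if len(population) else None
    areas = np.array([g.area for g in geoms]) if geoms else None
    tree = STRtree(geoms) if geoms else None
    for r in buffers_m:
        vals = np.zeros(len(mids))
        if tree is not None:
            for i, m in enumerate(mids):
                buf = m.buffer(r, quad_segs=_BUFFER_QUAD_SEGS)
                for j in tree.query(buf):
                    frac = buf.intersection(tree.geometries[j]).area / areas[j]
                    vals[i] += counts[j] * frac
        cols[f"population_{r}"] = vals
    return pd.DataFrame(cols, index=segments["segment_id"].to_numpy())


def build_feature_table(segments: pd.DataFrame, landuse: pd.DataFrame,
                        roads: pd.DataFrame, population: pd.DataFrame,
                        area_buffers=AREA_BUFFERS_M,
                        traffic_buffers=TRAFFIC_BUFFERS_M) -> pd.DataFrame:
    """Concatenate the three feature groups into one table keyed by segment_id."""
    parts = [
        buffer_area_features(segments, landuse, buffers_m=area_buffers),
        traffic_features(segments, roads, buffers_m=traffic_buffers),
        population_features(segments, population, buffers_m=area_buffers),
    ]
    table = pd.concat(parts, axis=1)
    table.index.name = "segment_id"
    table = table.sort_index()
    if table.isna().any().any():
        raise AssertionError("feature table contains missing values")
    return table


def check_identical_columns(tables: dict[str, pd.DataFrame]) -> None:
    """Raise if cities' feature tables differ in columns (names the offenders)."""
    items = list(tables.items())
    ref_city, ref = items[0]
    for city, tab in items[1:]:
        if list(tab.columns) != list(ref.columns):
            extra = sorted(set(tab.columns) - set(ref.columns))
            miss = sorted(set(ref.columns) - set(tab.columns))
            raise ValueError(
                f"feature columns of {city!r} differ from {ref_city!r}: "
                f"extra={extra}, missing={miss}, or ordering differs")


def column_schema(table: pd.DataFrame) -> list[dict]:
    """Sidecar schema: (column, group, class/statistic, buffer) per column."""
    schema = []
    for col in table.columns:
        parts = col.rsplit("_", 1)
        buffer_m = int(parts[1]) if parts[-1].isdigit() else None
        base = parts[0] if buffer_m is not None else col
        if base.startswith(("traffic", "hd_traffic", "roadlength")):
            group = "traffic"
        elif base.startswith("population"):
            group = "population"
        else:
            group = "land_use"
        schema.append({"column": col, "group": group, "base": base,
                       "buffer_m": buffer_m})
    return schema


def write_feature_table(table: pd.DataFrame, path, schema_path=None) -> None:
    """CSV round-trip at full float precision, plus an optional JSON schema."""
    table.to_csv(path, float_format="%.17g")
    if schema_path is not None:
        with open(schema_path, "w") as fh:
            json.dump(column_schema(table), fh, indent=2)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="segment_id").astype(float)
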