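"""Mobile-monitoring preprocessing: raw 1-Hz readings -> per-segment annual values.

The pipeline is the standard mobile-campaign chain:

1. ``filter_range``     — drop physically unrealistic 1-s values;
2. ``winsorize``        — clamp the campaign-wide value distribution at the
                          2.5th / 97.5th percentiles;
3. ``temporal_correct`` — remove hour-to-hour background variation using a
                          fixed reference site (NO2 only);
4. ``snap_to_segments`` — assign each GPS point to the nearest ~50 m road
                          segment;
5. ``mean_of_means``    — average readings within each drive day per segment,
                          then average the daily means.

Readings are pandas DataFrames with columns
``reading_id, time, lon, lat, pollutant, value`` (plus ``drive_day`` derived
from ``time`` and, after snapping, ``segment_id`` / ``snap_dist_m``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

#: plausibility bounds per pollutant, inclusive: NO2 in ug/m3, UFP in particles/cm3
VALUE_RANGES = {
    "NO2": (0.0, 500.0),
    "UFP": (250.0, 500_000.0),
}

#: winsorizing percentiles applied campaign-wide per pollutant per city
WINSOR_LIMITS = (2.5, 97.5)

#: default GPS-to-segment snap threshold, meters (half a segment + GPS error)
DEFAULT_MAX_SNAP_M = 35.0


def _require_pollutant(pollutant: str) -> tuple[float, float]:
    try:
        return VALUE_RANGES[pollutant]
    except KeyError:
        raise ValueError(
            f"unknown pollutant {pollutant!r}; expected one of {sorted(VALUE_RANGES)}"
        ) from None


def add_drive_day(readings: pd.DataFrame) -> pd.DataFrame:
    """Derive the drive-day label (calendar date of ``time``)."""
    out = readings.copy()
    out["drive_day"] = pd.to_datetime(out["time"]).dt.date
    return out


def filter_range(readings: pd.DataFrame, pollutant: str) -> pd.DataFrame:
    """Drop unrealistic 1-s values; bounds are inclusive, order preserved."""
    lo, hi = _require_pollutant(pollutant)
    mask = (readings["value"] >= lo) & (readings["value"] <= hi)
    return readings.loc[mask].copy()


def winsorize(values, limits: tuple[float, float] = WINSOR_LIMITS) -> np.ndarray:
    """Clamp values outside the (2.5th, 97.5th) percentiles to those percentiles.

    Percentiles are computed on the input itself with linear interpolation
    between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values passed to winsorize")
    lo, hi = np.percentile(v, limits, method="linear")
    return np.clip(v, lo, hi)


def temporal_correct(readings: pd.DataFrame, reference: pd.Series,
                     pollutant: str = "NO2", method: str = "additive") -> pd.DataFrame:
    """Remove hourly background variation using a fixed reference site.

    Each reading is adjusted additively by the deviation of the reference
    site in its hour from the campaign-wide reference mean:

        value' = value - (ref[hour] - mean(ref))

    Only NO2 is corrected (no routine UFP reference site exists); any other
    pollutant passes through unchanged. ``reference`` is indexed by hourly
    timestamps and must cover every reading hour.
    """
    if method == "none" or pollutant != "NO2":
        return readings.copy()
    if method != "additive":
        raise ValueError(f"unknown temporal correction method {method!r}")

    out = readings.copy()
    hours = pd.to_datetime(out["time"]).dt.floor("h")
    ref = reference.copy()
    ref.index = pd.to_datetime(ref.index)
    missing = pd.Index(hours.unique()).difference(ref.index)
    if len(missing) > 0:
        raise ValueError(
            "reference series missing hours: "
            + ", ".join(str(h) for h in sorted(missing)[:10])
        )
    deviation = ref.reindex(hours).to_numpy() - ref.mean()
    out["value"] = out["value"].to_numpy() - deviation
    return out


def snap_to_segments(readings: pd.DataFrame, segments: pd.DataFrame,
                     max_snap_m: float = DEFAULT_MAX_SNAP_M) -> pd.DataFrame:
    """Assign each reading to its nearest road segment by perpendicular distance.

    Readings farther than ``max_snap_m`` from every segment are dropped;
    equidistant ties go to the smallest segment_id. ``readings`` must carry
    planar-metric coordinates in columns ``x, y`` (see
    :class:`transferlur.geo.LocalProjection`); ``segments`` carries metric
    shapely geometries.
    """
    if len(segments) == 0:
        raise ValueError("empty segment set")
    from shapely.geometry import Point

    seg_ids = segments["segment_id"].to_numpy()
    tree = STRtree(list(segments["geometry"]))
    pts = [Point(x, y) for x, y in zip(readings["x"], readings["y"])]

    assigned = np.full(len(pts), -1, dtype=object)
    dists = np.full(len(pts), np.nan)
    if pts:
        pt_idx, seg_idx = tree.query_nearest(
            pts, max_distance=max_snap_m, all_matches=True, return_distance=False)
        # distances recomputed per candidate pair to break ties by segment_id
        d = np.array([pts[i].distance(tree.geometries[j])
                      for i, j in zip(pt_idx, seg_idx)])
        for i in np.unique(pt_idx):
            sel = pt_idx == i
            dmin = d[sel].min()
            if dmin > max_snap_m:
                continue
            cand = seg_idx[sel][d[sel] <= dmin + 1e-9]
            assigned[i] = min(seg_ids[cand])
            dists[i] = dmin

    out = readings.copy()
    out["segment_id"] = assigned
    out["snap_dist_m"] = dists
    keep = out["segment_id"] != -1
    return out.loc[keep].copy()


def mean_of_means(snapped: pd.DataFrame, pollutant: str | None = None) -> pd.DataFrame:
    """Aggregate snapped readings to per-segment annual values.

    Per segment: mean of readings within each drive day, then the unweighted
    mean over drive-day means ("mean of means"). ``n_drive_pass`` is the
    number of distinct drive days, ``n_points`` the number of contributing
    readings. Segments without readings are simply absent.
    """
    if pollutant is None:
        pollutants = snapped["pollutant"].unique()
        if len(pollutants) != 1:
            raise ValueError("mixed pollutants; pass `pollutant` explicitly")
        pollutant = pollutants[0]

    daily = (snapped.groupby(["segment_id", "drive_day"], sort=True)["value"]
             .agg(["mean", "size"]))
    agg = daily.groupby(level="segment_id").agg(
        value=("mean", "mean"),
        n_drive_pass=("mean", "size"),
        n_points=("size", "sum"),
    ).reset_index()
    agg.insert(1, "pollutant", pollutant)
    return agg


def preprocess_campaign(readings: pd.DataFrame, segments: pd.DataFrame,
                        pollutant: str, reference: pd.Series | None = None,
                        max_snap_m: float = DEFAULT_MAX_SNAP_M,
                        temporal_method: str = "additive") -> tuple[pd.DataFrame, dict]:
    """Run the full preprocessing chain; returns (aggregates, provenance).

    Provenance records the record counts entering/leaving each stage.
    """
    prov: dict = {"pollutant": pollutant, "n_raw": int(len(readings))}
    r = add_drive_day(readings)
    r = r[r["pollutant"] == pollutant]
    prov["n_pollutant"] = int(len(r))
    r = filter_range(r, pollutant)
    prov["n_after_range_filter"] = int(len(r))
    prov["n_removed_range_filter"] = prov["n_pollutant"] - prov["n_after_range_filter"]
    if len(r) > 0:
        r = r.assign(value=winsorize(r["value"].to_numpy()))
    if reference is not None:
        r = temporal_correct(r, reference, pollutant=pollutant, method=temporal_method)
    r = snap_to_segments(r, segments, max_snap_m=max_snap_m)
    prov["n_snapped"] = int(len(r))
    prov["n_dropped_snap"] = prov["n_after_range_filter"] - prov["n_snapped"]
    agg = mean_of_means(r, pollutant=pollutant)
    prov["n_segments_measured"] = int(len(agg))
    prov["mean_drive_pass"] = float(agg["n_drive_pass"].mean()) if len(agg) else 0.0
    return agg, prov
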