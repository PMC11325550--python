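"""Model-evaluation suite for long-term exposure predictions.

Conventions that matter and are easy to get wrong:

* ``r2`` is the **squared Pearson correlation** between predictions and
  observations, not 1 - SSE/SST. The two differ whenever predictions are
  biased; squared-correlation R2 is the convention in mobile-monitoring
  LUR validation.
* ``ccc`` is Lin's concordance correlation coefficient computed with
  population (1/n) moments:

      CCC = 2 rho sx sy / (sx^2 + sy^2 + (mx - my)^2)

  It penalises both lack of correlation and systematic bias, so an
  affine-perfect prediction (pred = a*obs + b) has R2 = 1 but CCC < 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.strtree import STRtree


@dataclass
class EvalReport:
    n: int
    r2: float
    mae: float
    rmse: float
    pearson_r: float
    ccc: float
    residuals: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "r2": float(self.r2),
            "mae": float(self.mae),
            "rmse": float(self.rmse),
            "pearson_r": float(self.pearson_r),
            "ccc": float(self.ccc),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_row(self, model: str = "") -> pd.DataFrame:
        """One-row summary table (model, R2, MAE, RMSE)."""
        return pd.DataFrame(
            [{"model": model, "R2": self.r2, "MAE": self.mae, "RMSE": self.rmse}]
        )


def concordance_ccc(pred, obs) -> float:
    """Lin's CCC with population (1/n) moments."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population variances
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return np.nan
    return 2.0 * cov / denom


def evaluate(pred, obs) -> EvalReport:
    """Compare predictions with observations.

    If either vector has zero variance the correlation-based metrics are
    undefined: ``r2``, ``pearson_r`` and ``ccc`` are reported as NaN with a
    warning, while MAE/RMSE are still computed.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValueError("non-finite values in pred/obs")

    resid = pred - obs
    mae = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid**2).mean()))

    if pred.std() == 0.0 or obs.std() == 0.0:
        warnings.warn("zero variance: correlation metrics undefined (NaN)")
        r = r2 = ccc = np.nan
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
        r2 = r**2
        ccc = float(concordance_ccc(pred, obs))
    return EvalReport(n=pred.size, r2=r2, mae=mae, rmse=rmse,
                      pearson_r=r, ccc=ccc, residuals=resid)


def match_validation_sites(sites: pd.DataFrame, segments: pd.DataFrame,
                           max_match_m: float = 20.0) -> pd.DataFrame:
    """Pair fixed validation sites with their nearest road segment.

    Sites farther than ``max_match_m`` (default 20 m) from every segment are
    excluded. Equidistant ties go to the lexicographically smallest
    segment_id. Both frames carry planar-metric shapely geometries in a
    ``geometry`` column; sites need ``site_id`` and ``value``.

    Returns a frame with columns site_id, segment_id, distance_m, value.
    """
    seg_geoms = list(segments["geometry"])
    seg_ids = segments["segment_id"].to_numpy()
    tree = STRtree(seg_geoms)
    rows = []
    for site in sites.itertuples(index=False):
        idx, dist = tree.query_nearest(
            site.geometry, max_distance=max_match_m, return_distance=True,
            all_matches=True)
        if len(idx) == 0:
            continue
        dmin = dist.min()
        at_min = idx[dist <= dmin + 1e-9]
        seg = min(seg_ids[at_min])
        rows.append({"site_id": site.site_id, "segment_id": seg,
                     "distance_m": float(dmin), "value": site.value})
    return pd.DataFrame(rows, columns=["site_id", "segment_id", "distance_m", "value"])
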