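"""Inverse-distance-weighted fusion of per-source-city transfer models.

Emission patterns (the conditional relation between land-use predictors and
concentrations) resemble those of nearby cities more than distant ones
(Tobler's first law). Lacking target measurements to recalibrate with, the
ensemble therefore weights each source city's fitted model by the inverse
of its straight-line distance to the target city,

    w_i = d_i^{-p} / sum_j d_j^{-p},    p = 1 by default,

and applies those weights homogeneously to every target segment. The layer
is model-agnostic: members may be CORAL models (IDW_Coral) or directly
applied SLR models (IDW_SLR).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .coral import CoralModel, predict_coral
from .geo import haversine_km
from .slr import SLRModel, predict_slr

__all__ = ["CityLocation", "IDWEnsemble", "idw_weights", "fit_idw_ensemble",
           "predict_idw", "predict_member"]


@dataclass(frozen=True)
class CityLocation:
    city_id: str
    lon: float
    lat: float

    def distance_km(self, other: "CityLocation") -> float:
        return float(haversine_km(self.lon, self.lat, other.lon, other.lat))


def idw_weights(distances_km, p: float = 1.0) -> np.ndarray:
    """Normalised inverse-distance weights w_i = d_i^-p / sum d_j^-p."""
    d = np.asarray(distances_km, dtype=float)
    if d.size == 0:
        raise ValueError("at least one source distance required")
    if np.any(d <= 0):
        raise ValueError("distances must be positive (a zero distance means the "
                         "source city is the target; no transfer is needed)")
    w = d ** (-p)
    return w / w.sum()


def predict_member(model, X):
    """Dispatch prediction for either model family."""
    if isinstance(model, CoralModel):
        return predict_coral(model, X)
    if isinstance(model, SLRModel):
        return predict_slr(model, X)
    raise TypeError(f"unsupported member model type: {type(model).__name__}")


@dataclass
class IDWEnsemble:
    """Per-source models with fixed, segment-independent IDW weights."""

    members: list[tuple[str, object, float]]  # (source city_id, model, weight)
    p: float
    target_city: str

    def describe(self) -> dict:
        return {"target_city": self.target_city, "p": self.p,
                "members": [{"city_id": c, "model": type(m).__name__,
                             "weight": w} for c, m, w in self.members]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.describe(), fh, indent=2)


def fit_idw_ensemble(models: dict[str, object], locations: dict[str, CityLocation],
                     target_city: str, p: float = 1.0,
                     distances_km: dict[str, float] | None = None) -> IDWEnsemble:
    """Assemble per-source models into a distance-weighted ensemble.

    Distances default to great-circle distances between declared city
    centroids; explicit straight-line ``distances_km`` overrides take
    precedence when supplied.
    """
    if not models:
        raise ValueError("no member models supplied")
    cities = sorted(models)
    target = locations[target_city]
    dists = []
    for c in cities:
        if distances_km is not None and c in distances_km:
            d = float(distances_km[c])
        else:
            d = locations[c].distance_km(target)
        dists.append(d)
    w = idw_weights(np.array(dists), p=p)
    members = [(c, models[c], float(wi)) for c, wi in zip(cities, w)]
    return IDWEnsemble(members=members, p=p, target_city=target_city)


def predict_idw(ensemble: IDWEnsemble, X_t) -> np.ndarray:
    """Weighted sum of member predictions; a convex combination per segment."""
    preds = [w * predict_member(m, X_t) for _, m, w in ensemble.members]
    return np.sum(preds, axis=0)
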