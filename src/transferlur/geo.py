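"""Small geodesy helpers: great-circle distances and a local metric projection.

All pipeline geometry (snapping, buffering) happens in a planar metric
coordinate system. City extents here are ~10-20 km, where a local
equirectangular projection centred on the study area is accurate to well
under GPS error, so no external CRS machinery is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 points (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection centred at (lon0, lat0), in meters.

    x = R * cos(lat0) * dlon, y = R * dlat. Suitable for city-scale
    extents; distance distortion is O((extent / R)^2).
    """

    lon0: float
    lat0: float

    def to_xy(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        r_m = EARTH_RADIUS_KM * 1000.0
        x = r_m * math.cos(math.radians(self.lat0)) * np.radians(lon - self.lon0)
        y = r_m * np.radians(lat - self.lat0)
        return x, y

    def to_lonlat(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r_m = EARTH_RADIUS_KM * 1000.0
        lon = self.lon0 + np.degrees(x / (r_m * math.cos(math.radians(self.lat0))))
        lat = self.lat0 + np.degrees(y / r_m)
        return lon, lat
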