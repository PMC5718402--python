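"""Great-circle geometry on the WGS84 mean sphere.

All distances are in kilometres, all angles in degrees unless noted.
Radius follows the IUGG mean radius, 6371.009 km.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.009


def normalize_lon(lon):
    """Normalize longitudes to (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    out = np.where(out == -180.0, 180.0, out)
    return out if out.ndim else float(out)


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km. Symmetric, non-negative, d(p, p) = 0."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing, clockwise from true north, in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    b = np.degrees(np.arctan2(y, x)) % 360.0
    return b if np.ndim(b) else float(b)


def destination(lon, lat, bearing_deg, dist_km):
    """Point reached travelling dist_km along the initial bearing."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(brg))
    lon2 = lon1 + np.arctan2(np.sin(brg) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    lon_out = normalize_lon(np.degrees(lon2))
    lat_out = np.degrees(lat2)
    if np.ndim(lat_out):
        return lon_out, lat_out
    return float(lon_out), float(lat_out)


def intermediate_point(lon1, lat1, lon2, lat2, frac):
    """Point a fraction ``frac`` of the way along the great circle from p1 to p2."""
    d = haversine_km(lon1, lat1, lon2, lat2)
    if np.ndim(d) == 0 and d == 0.0:
        return float(lon1), float(lat1)
    b = initial_bearing_deg(lon1, lat1, lon2, lat2)
    return destination(lon1, lat1, b, np.asarray(frac) * d)


class LocalProjection:
    """Azimuthal-equidistant-style tangent plane centred at (lon0, lat0).

    Adequate for the few-thousand-km scales of pinniped tracks; used by the
    state-space smoother, which needs a locally Euclidean frame.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._coslat0 = np.cos(np.radians(lat0))

    def forward(self, lon, lat):
        """Degrees -> km east/north of the centre."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        dlon = np.radians(normalize_lon(lon - self.lon0))
        x = EARTH_RADIUS_KM * dlon * self._coslat0
        y = EARTH_RADIUS_KM * np.radians(lat - self.lat0)
        return x, y

    def inverse(self, x, y):
        """km east/north -> degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.lat0 + np.degrees(y / EARTH_RADIUS_KM)
        lon = self.lon0 + np.degrees(x / (EARTH_RADIUS_KM * self._coslat0))
        return normalize_lon(lon), lat
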