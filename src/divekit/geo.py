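"""Great-circle geometry helpers on a spherical Earth.

All distances are haversine distances on a sphere of radius 6,371,000 m,
which is accurate to ~0.5% against the ellipsoid at the scales involved
(hundreds of metres to tens of kilometres).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points given in degrees.

    Accepts scalars or broadcastable arrays; returns the same shape.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    if np.isscalar(lon1) or d.ndim == 0:
        return float(d)
    return d


def metres_per_degree(lat_deg):
    """(metres per degree of longitude, metres per degree of latitude) at ``lat_deg``."""
    m_per_deg_lat = np.pi / 180.0 * EARTH_RADIUS_M
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(np.asarray(lat_deg, dtype=float)))
    return m_per_deg_lon, m_per_deg_lat


def offset_lonlat(lon: float, lat: float, east_m, north_m):
    """Displace a lon/lat point by metric offsets using the local scale at ``lat``."""
    m_lon, m_lat = metres_per_degree(lat)
    return lon + np.asarray(east_m) / m_lon, lat + np.asarray(north_m) / m_lat


def track_distance_m(lons, lats) -> float:
    """Summed consecutive-fix great-circle distance along a polyline."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 2:
        return 0.0
    return float(np.sum(haversine_m(lons[:-1], lats[:-1], lons[1:], lats[1:])))
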