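"""Great-circle geometry helpers on WGS84 decimal degrees.

All distances are in meters. Local displacements (simulation, GPS noise)
use an equirectangular tangent-plane approximation, which is accurate to
well under 1 m over the few-kilometer scales this package deals with.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6371008.8  # mean Earth radius


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance between points, elementwise over array inputs."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def offset_latlon(lat: float, lon: float, dnorth_m, deast_m):
    """Displace (lat, lon) by meters north/east in the local tangent plane."""
    dnorth_m = np.asarray(dnorth_m, dtype=float)
    deast_m = np.asarray(deast_m, dtype=float)
    dlat = np.degrees(dnorth_m / EARTH_RADIUS_M)
    dlon = np.degrees(deast_m / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
    return lat + dlat, lon + dlon


def polyline_length_m(lats: np.ndarray, lons: np.ndarray) -> float:
    """Total arc length of a latitude/longitude polyline."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size < 2:
        return 0.0
    seg = haversine_m(lats[:-1], lons[:-1], lats[1:], lons[1:])
    return float(np.sum(seg))
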