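"""Small geodesy helpers shared across the package.

All coordinates are WGS84 lon/lat degrees; local metre<->degree conversion
uses equirectangular scaling (1 deg lat = R*pi/180 m; 1 deg lon scales with
cos(lat)).  At fjord scales the error is far below the 2 km settlement
radius, which is the only length scale decisions depend on.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

_DEG = np.pi / 180.0
#: metres per degree of latitude
M_PER_DEG_LAT = EARTH_RADIUS_M * _DEG


def m_per_deg_lon(lat_deg):
    """Metres per degree of longitude at latitude ``lat_deg``."""
    return EARTH_RADIUS_M * _DEG * np.cos(np.asarray(lat_deg) * _DEG)


def metres_to_degrees(dx_m, dy_m, lat_deg):
    """Convert local metre offsets to (dlon, dlat) degree offsets."""
    dlat = np.asarray(dy_m) / M_PER_DEG_LAT
    dlon = np.asarray(dx_m) / m_per_deg_lon(lat_deg)
    return dlon, dlat


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres (broadcasts over array inputs)."""
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) * _DEG for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
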