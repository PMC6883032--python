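"""Great-circle distances on a spherical Earth.

A sphere of radius 6371 km is accurate to ~0.5% — irrelevant at the 100-km
neighborhood scale the upscaling uses.
"""

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in WGS84 decimal degrees.

    Accepts scalars or broadcastable arrays; returns the same shape.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards tiny negative/overshoot from rounding at antipodal/zero distance
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d
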