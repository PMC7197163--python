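"""Solar elevation for diel (day/night) classification.

NOAA's low-precision solar position algorithm: adequate to a fraction of a
degree, which is far finer than a 2-4 h fix schedule needs. Timestamps are
UTC; the site defaults to the semi-arid study region (26.23 deg S,
121.56 deg E).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SITE_LAT = -26.23
SITE_LON = 121.56

__all__ = ["solar_elevation_deg", "is_diurnal", "SITE_LAT", "SITE_LON"]


def solar_elevation_deg(timestamps, lat: float = SITE_LAT,
                        lon: float = SITE_LON) -> np.ndarray:
    """Solar elevation angle in degrees for UTC timestamps (vectorized)."""
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    doy = ts.dayofyear.to_numpy()
    hours = (ts.hour + ts.minute / 60 + ts.second / 3600).to_numpy(dtype=float)
    # fractional year (radians)
    gamma = 2 * np.pi / 365 * (doy - 1 + (hours - 12) / 24)
    eqtime = 229.18 * (
        0.000075 + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma)
    )  # minutes
    decl = (
        0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma)
    )  # radians
    time_offset = eqtime + 4 * lon  # minutes (UTC; no zone correction)
    tst = hours * 60 + time_offset
    ha = np.deg2rad(tst / 4 - 180)  # hour angle
    lat_r = np.deg2rad(lat)
    cos_zen = (np.sin(lat_r) * np.sin(decl)
               + np.cos(lat_r) * np.cos(decl) * np.cos(ha))
    return 90.0 - np.rad2deg(np.arccos(np.clip(cos_zen, -1, 1)))


def is_diurnal(timestamps, lat: float = SITE_LAT,
               lon: float = SITE_LON) -> np.ndarray:
    """True where the sun is above the horizon at the site."""
    return solar_elevation_deg(timestamps, lat, lon) > 0.0
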