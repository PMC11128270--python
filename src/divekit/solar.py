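"""Solar elevation by the NOAA low-precision algorithm.

Good to a fraction of a degree, which is ample for day/night flagging and
sunrise/sunset scheduling. All inputs are UTC; longitudes are positive east.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def solar_elevation_deg(times_utc, lon, lat):
    """Solar elevation angle (degrees above horizon) at given UTC instants.

    Parameters
    ----------
    times_utc : datetime-like scalar or sequence (naive values are taken as UTC)
    lon, lat : position in decimal degrees (scalar or broadcastable arrays)

    Returns
    -------
    float or ndarray of elevations in degrees; > 0 means the sun is up.
    """
    t = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(times_utc)))
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    doy = t.dayofyear.to_numpy(dtype=float)
    frac_hour = (t.hour + t.minute / 60.0 + t.second / 3600.0
                 + t.microsecond / 3.6e9).to_numpy(dtype=float)

    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (frac_hour - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075
                       + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918
            - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))

    lon = np.asarray(lon, dtype=float)
    lat_r = np.radians(np.asarray(lat, dtype=float))
    tst = frac_hour * 60.0 + eqtime + 4.0 * lon  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)           # hour angle
    cos_zen = (np.sin(lat_r) * np.sin(decl)
               + np.cos(lat_r) * np.cos(decl) * np.cos(ha))
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    return elev if elev.size > 1 else float(elev[0])


def is_daylight(times_utc, lon, lat):
    """True where solar elevation is strictly above the horizon."""
    e = solar_elevation_deg(times_utc, lon, lat)
    return e > 0.0


def sun_window_utc(date_utc, lon, lat, step_s: int = 300):
    """(sunrise, sunset) UTC for the local solar day containing noon at ``lon``.

    Scans solar elevation on a ``step_s`` grid over a 24 h window centred on
    local solar noon; returns pandas Timestamps (UTC-naive). If the sun never
    rises/sets, returns (None, None).
    """
    day = pd.Timestamp(date_utc).normalize()
    # local solar noon in UTC is ~12h minus lon/15 h
    noon = day + pd.Timedelta(hours=12.0 - float(lon) / 15.0)
    grid = pd.date_range(noon - pd.Timedelta(hours=12), noon + pd.Timedelta(hours=12),
                         freq=f"{step_s}s")
    elev = solar_elevation_deg(grid, lon, lat)
    up = np.asarray(elev) > 0.0
    if not up.any() or up.all():
        return None, None
    idx = np.nonzero(up)[0]
    return grid[idx[0]], grid[idx[-1]]
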