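"""Solar geometry for photoperiod splitting.

Implements the NOAA solar-position equations (Julian century polynomial for
the solar ephemeris, equation of time, hour angle) to decide whether the sun's
centre is above the horizon at a given place and instant.  Accuracy is a few
hundredths of a degree in elevation — far finer than the hourly fix spacing
the day/night flags are applied to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _julian_century(times_utc: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    ts = pd.DatetimeIndex(times_utc)
    jd = ts.to_julian_date().to_numpy(dtype=float)
    return (jd - 2451545.0) / 36525.0


def solar_elevation(lat: float, lon: float, times_utc) -> np.ndarray:
    """Solar elevation angle (degrees) at (lat, lon) for tz-aware UTC times."""
    t = _julian_century(times_utc)
    # geometric mean longitude / anomaly of the sun (degrees)
    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = np.radians(m)
    eq_ctr = (np.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
              + np.sin(2 * mrad) * (0.019993 - 0.000101 * t)
              + np.sin(3 * mrad) * 0.000289)
    true_long = l0 + eq_ctr
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.radians(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(np.radians(omega))
    declination = np.degrees(
        np.arcsin(np.sin(np.radians(obliq)) * np.sin(np.radians(app_long)))
    )
    var_y = np.tan(np.radians(obliq / 2.0)) ** 2
    eq_time = 4.0 * np.degrees(
        var_y * np.sin(2 * np.radians(l0))
        - 2 * e * np.sin(mrad)
        + 4 * e * var_y * np.sin(mrad) * np.cos(2 * np.radians(l0))
        - 0.5 * var_y ** 2 * np.sin(4 * np.radians(l0))
        - 1.25 * e ** 2 * np.sin(2 * mrad)
    )
    ts = pd.DatetimeIndex(times_utc)
    minutes_utc = (ts.hour * 60 + ts.minute + ts.second / 60.0).to_numpy(dtype=float)
    true_solar_min = np.mod(minutes_utc + eq_time + 4.0 * lon, 1440.0)
    hour_angle = np.where(true_solar_min / 4.0 < 0.0,
                          true_solar_min / 4.0 + 180.0,
                          true_solar_min / 4.0 - 180.0)
    phi = np.radians(lat)
    decl = np.radians(declination)
    cos_zenith = (np.sin(phi) * np.sin(decl)
                  + np.cos(phi) * np.cos(decl) * np.cos(np.radians(hour_angle)))
    return 90.0 - np.degrees(np.arccos(np.clip(cos_zenith, -1.0, 1.0)))


def day_flags(lat: float, lon: float, times_utc) -> np.ndarray:
    """Boolean per-time flag: True where the sun's centre is above the horizon.

    Near the poles a whole day may be all-day or all-night; in that case the
    flags fall back to a fixed 06:00-18:00 local-solar-time day so that
    day/night feature subsets stay populated.
    """
    elev = solar_elevation(lat, lon, times_utc)
    flags = elev > 0.0
    if flags.all() or (~flags).all():
        ts = pd.DatetimeIndex(times_utc)
        local_solar_hour = np.mod(
            ts.hour + ts.minute / 60.0 + lon / 15.0, 24.0
        )
        flags = (local_solar_hour >= 6.0) & (local_solar_hour < 18.0)
    return flags
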