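"""Sunrise, sunset, and civil twilight times (NOAA solar position algorithm).

Implements the low-precision NOAA formulas (fractional-year Fourier
expansions of the equation of time and solar declination) which are
accurate to about one minute at mid-latitudes — far finer than the
one-hour diel windows built on top of them.  Latitudes above 60° are
rejected: midnight-sun/polar-night bookkeeping is out of scope for a
coastal study site.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

ZENITH_OFFICIAL = 90.833  # degrees; sunrise/sunset including refraction
ZENITH_CIVIL = 96.0       # degrees; civil twilight

MAX_LAT = 60.0


def _fractional_year(date: dt.date) -> float:
    doy = date.timetuple().tm_yday
    year_len = 366 if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0) else 365
    return 2.0 * np.pi / year_len * (doy - 1 + 0.5)


def _equation_of_time_min(g: float) -> float:
    return 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                     - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))


def _declination_rad(g: float) -> float:
    return (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))


def _hour_angle_deg(lat: float, decl: float, zenith: float) -> float:
    lat_r = np.radians(lat)
    cos_ha = (np.cos(np.radians(zenith)) / (np.cos(lat_r) * np.cos(decl))
              - np.tan(lat_r) * np.tan(decl))
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(
            f"sun never crosses zenith {zenith}° at latitude {lat}° on this date")
    return np.degrees(np.arccos(cos_ha))


def sun_events_utc(date: dt.date, lat: float, lon: float) -> dict[str, pd.Timestamp]:
    """Civil dawn, sunrise, sunset, and civil dusk (UTC) for a calendar date.

    ``date`` is the local civil date of interest; the returned instants are
    tz-aware UTC timestamps.  Longitude is positive east.
    """
    if abs(lat) > MAX_LAT:
        raise ValueError(f"latitude {lat}° beyond supported |lat| <= {MAX_LAT}°")
    g = _fractional_year(date)
    eqtime = _equation_of_time_min(g)
    decl = _declination_rad(g)

    def event(zenith: float, rising: bool) -> pd.Timestamp:
        ha = _hour_angle_deg(lat, decl, zenith)
        minutes = 720.0 - 4.0 * (lon + (ha if rising else -ha)) - eqtime
        base = pd.Timestamp(date, tz="UTC")
        return base + pd.Timedelta(minutes=minutes)

    return {
        "civil_dawn": event(ZENITH_CIVIL, rising=True),
        "sunrise": event(ZENITH_OFFICIAL, rising=True),
        "sunset": event(ZENITH_OFFICIAL, rising=False),
        "civil_dusk": event(ZENITH_CIVIL, rising=False),
    }
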