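"""Solar geometry and top-of-atmosphere potential shortwave radiation.

Potential radiation (``SW_IN_POT``) is the timing and magnitude reference
for the data checks: the timestamp-alignment detector cross-correlates
measured shortwave against it, the radiation checks use it as a ceiling,
and "night" is defined as ``SW_IN_POT == 0`` so the definition stays robust
to radiation-sensor faults.

Declination and the equation of time use the Astronomical Almanac
low-precision solar ephemeris (accurate to ~0.01 deg), the eccentricity
factor uses Spencer's series (3-decimal accuracy is ample for a radiation
ceiling).  Radiation is evaluated at interval *midpoints* so that a
beginning-vs-ending timestamp confusion appears as exactly a one-interval
lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fp_format import SiteMetadata

SOLAR_CONSTANT = 1361.0  # W m-2


@dataclass(frozen=True)
class SolarGeometry:
    """Per-instant solar angles (radians) and the equation of time (minutes)."""

    declination: np.ndarray
    equation_of_time: np.ndarray
    hour_angle: np.ndarray
    zenith: np.ndarray


def _day_angle(times: pd.DatetimeIndex) -> np.ndarray:
    """Fractional day-of-year angle gamma in radians (Spencer convention,
    made leap-aware so the orbital phase does not drift across years)."""
    doy = times.dayofyear.to_numpy().astype(float)
    frac = (times.hour.to_numpy() + times.minute.to_numpy() / 60.0) / 24.0
    year_len = np.where(times.is_leap_year, 366.0, 365.0)
    return 2.0 * np.pi * (doy - 1 + frac) / year_len


def _sun_coordinates(times: pd.DatetimeIndex, utc_offset_hours: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Declination (radians) and equation of time (minutes) from the
    Astronomical Almanac low-precision solar ephemeris."""
    utc = times - pd.Timedelta(hours=utc_offset_hours)
    n = (utc - pd.Timestamp("2000-01-01 12:00")).total_seconds().to_numpy() / 86400.0
    mean_lon = np.mod(280.460 + 0.9856474 * n, 360.0)
    g = np.deg2rad(np.mod(357.528 + 0.9856003 * n, 360.0))
    ecliptic_lon = np.deg2rad(mean_lon + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    obliquity = np.deg2rad(23.439 - 4.0e-7 * n)
    decl = np.arcsin(np.sin(obliquity) * np.sin(ecliptic_lon))
    ra = np.rad2deg(np.arctan2(np.cos(obliquity) * np.sin(ecliptic_lon),
                               np.cos(ecliptic_lon)))
    eot_deg = np.mod(mean_lon - ra + 180.0, 360.0) - 180.0
    return decl, 4.0 * eot_deg


def declination(times: pd.DatetimeIndex, utc_offset_hours: float = 0.0) -> np.ndarray:
    """Solar declination (radians)."""
    return _sun_coordinates(pd.DatetimeIndex(times), utc_offset_hours)[0]


def equation_of_time(times: pd.DatetimeIndex, utc_offset_hours: float = 0.0
                     ) -> np.ndarray:
    """Equation of time (minutes)."""
    return _sun_coordinates(pd.DatetimeIndex(times), utc_offset_hours)[1]


def eccentricity_factor(times: pd.DatetimeIndex) -> np.ndarray:
    """Squared inverse relative Earth-Sun distance E0 (Spencer's series)."""
    g = _day_angle(times)
    return (1.000110 + 0.034221 * np.cos(g) + 0.001280 * np.sin(g)
            + 0.000719 * np.cos(2 * g) + 0.000077 * np.sin(2 * g))


def solar_position(site: SiteMetadata, times) -> SolarGeometry:
    """Solar geometry for each timestamp (local standard time) at a site.

    The hour angle combines local standard time, the site longitude's
    offset from the time-zone meridian, and the equation of time:
    ``cos(zenith) = sin(lat) sin(decl) + cos(lat) cos(decl) cos(h)``.
    """
    times = pd.DatetimeIndex(pd.to_datetime(times))
    lat = np.deg2rad(site.lat_deg)
    decl, eot = _sun_coordinates(times, site.utc_offset_hours)
    clock_minutes = (times.hour.to_numpy() * 60.0 + times.minute.to_numpy()
                     + times.second.to_numpy() / 60.0)
    # minutes of true solar time past local midnight
    solar_minutes = (clock_minutes + eot
                     + 4.0 * (site.lon_deg - 15.0 * site.utc_offset_hours))
    hour_angle = np.deg2rad((solar_minutes - 720.0) / 4.0)
    cos_z = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    zenith = np.arccos(np.clip(cos_z, -1.0, 1.0))
    return SolarGeometry(decl, eot, hour_angle, zenith)


def potential_radiation(site: SiteMetadata, start, resolution_minutes: int) -> np.ndarray:
    """Top-of-atmosphere shortwave (W m-2) at interval midpoints.

    ``SW_IN_POT = S0 * E0(doy) * max(cos(zenith), 0)``.  Because the value
    is a pointwise function of the midpoint instant, lag-shifting the
    timestamp axis shifts the series identically (the translation property
    the cross-correlation lag detector relies on).
    """
    starts = pd.DatetimeIndex(pd.to_datetime(start))
    mid = starts + pd.Timedelta(minutes=resolution_minutes / 2.0)
    geom = solar_position(site, mid)
    e0 = eccentricity_factor(mid)
    cos_z = np.cos(geom.zenith)
    return SOLAR_CONSTANT * e0 * np.maximum(cos_z, 0.0)


def day_length_hours(lat_deg: float, doy: int) -> float:
    """Closed-form astronomical day length (hours) for |lat| <= 66 deg."""
    g = 2.0 * np.pi * (doy - 1) / 365.0
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    lat = np.deg2rad(lat_deg)
    x = -np.tan(lat) * np.tan(decl)
    x = np.clip(x, -1.0, 1.0)
    return float(2.0 * np.rad2deg(np.arccos(x)) / 15.0)
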