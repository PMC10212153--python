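"""Solar and lunar geometry for diel-activity analysis.

The response statistic of the whole pipeline — *nocturnality* — is the
distance, in decimal hours on the 24-hour circle, between a detection
timestamp and the solar noon (solar transit) of its calendar date: 0 means
the animal was seen exactly at solar noon, 12 exactly at solar midnight.
Solar noon is computed from the NOAA general solar-position equations
(equation of time as a Fourier series in the fractional year, plus the
longitude and UTC-offset corrections); this is accurate to well under a
minute over the supported 1950-2100 range, far below the hour-scale response.

The lunar illuminated fraction (0 = new moon, 1 = full moon) is computed from
the standard low-precision series for the moon's phase angle (mean elongation
plus the leading anomaly terms), accurate to about 0.01 of illumination.

All timestamps handled here are naive local clock times under one fixed UTC
offset; daylight-saving transitions are deliberately not modelled (the offset
is a configuration value, so a study spanning a DST change can be run in
standard time throughout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SolarContext",
    "solar_noon",
    "nocturnality",
    "lunar_fraction",
]

_MIN_YEAR = 1950
_MAX_YEAR = 2100


@dataclass(frozen=True)
class SolarContext:
    """Location and clock convention for solar computations.

    Parameters
    ----------
    latitude, longitude : float
        Degrees; east longitude positive.
    utc_offset_hours : float
        Fixed signed offset of the local clock from UTC (e.g. -8.0 for
        Pacific Standard Time).
    """

    latitude: float
    longitude: float
    utc_offset_hours: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


def _as_datetimeindex(timestamps) -> pd.DatetimeIndex:
    if isinstance(timestamps, pd.DatetimeIndex):
        return timestamps
    if np.isscalar(timestamps) or isinstance(timestamps, (pd.Timestamp,)) or not isinstance(
        timestamps, (Iterable,)
    ):
        return pd.DatetimeIndex([pd.Timestamp(timestamps)])
    return pd.DatetimeIndex(pd.to_datetime(list(timestamps)))


def _check_year_range(years: np.ndarray) -> None:
    if years.min() < _MIN_YEAR or years.max() > _MAX_YEAR:
        raise ValueError(
            f"dates outside the supported {_MIN_YEAR}-{_MAX_YEAR} range of the "
            "solar-position approximation"
        )


def _equation_of_time_minutes(dates: pd.DatetimeIndex) -> np.ndarray:
    """NOAA Fourier-series equation of time, in minutes (apparent - mean sun)."""
    years = dates.year.to_numpy()
    _check_year_range(years)
    doy = dates.dayofyear.to_numpy().astype(float)
    leap = dates.is_leap_year
    days_in_year = np.where(leap, 366.0, 365.0)
    # fractional year, evaluated at local mid-day
    gamma = 2.0 * np.pi / days_in_year * (doy - 1.0 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2.0 * gamma)
        - 0.040849 * np.sin(2.0 * gamma)
    )
    return eqtime


def solar_noon(dates, ctx: SolarContext):
    """Local clock time of solar transit, in decimal hours.

    Parameters
    ----------
    dates : date-like or sequence of date-likes
        Calendar dates (time-of-day components are ignored).
    ctx : SolarContext

    Returns
    -------
    float or ndarray
        Decimal hours of local clock time (e.g. 12.17 = 12:10:12). Scalar in,
        scalar out.
    """
    idx = _as_datetimeindex(dates).normalize()
    eqtime = _equation_of_time_minutes(idx)
    noon_utc_minutes = 720.0 - 4.0 * ctx.longitude - eqtime
    local_minutes = noon_utc_minutes + 60.0 * ctx.utc_offset_hours
    hours = local_minutes / 60.0
    if np.ndim(dates) == 0 and not isinstance(dates, (list, tuple, np.ndarray, pd.Series, pd.DatetimeIndex)):
        return float(hours[0])
    return np.asarray(hours)


def nocturnality(timestamps, ctx: SolarContext):
    """Distance in decimal hours, on the 24 h circle, from the date's solar noon.

    ``min(|t - noon|, 24 - |t - noon|)``, guaranteed in [0, 12]; 0 at solar
    noon, 12 at solar midnight. Vectorised: scalar in, scalar out; sequence
    in, ndarray out.
    """
    scalar = np.ndim(timestamps) == 0 and not isinstance(
        timestamps, (list, tuple, np.ndarray, pd.Series, pd.DatetimeIndex)
    )
    idx = _as_datetimeindex(timestamps)
    clock_hours = (
        idx.hour.to_numpy()
        + idx.minute.to_numpy() / 60.0
        + idx.second.to_numpy() / 3600.0
        + idx.microsecond.to_numpy() / 3.6e9
    )
    noon = solar_noon(idx, ctx)
    delta = np.abs(clock_hours - np.asarray(noon))
    value = np.minimum(delta, 24.0 - delta)
    if scalar:
        return float(value[0])
    return value


# --- lunar illuminated fraction -------------------------------------------

def _julian_day(dt_utc: pd.DatetimeIndex) -> np.ndarray:
    epoch = pd.Timestamp("2000-01-01 12:00:00")
    days = (dt_utc - epoch) / pd.Timedelta(days=1)
    return 2451545.0 + days.to_numpy()


def lunar_fraction(timestamps, utc_offset_hours: float = 0.0):
    """Illuminated fraction of the moon's disk, in [0, 1].

    0 = new moon, 1 = full moon. ``timestamps`` are naive local clock times;
    ``utc_offset_hours`` converts them to UTC for the ephemeris. Uses the
    low-precision phase-angle series (mean elongation of the moon corrected by
    the leading solar and lunar anomaly terms); the illuminated fraction is
    ``(1 + cos i) / 2`` with ``i`` the phase angle.
    """
    scalar = np.ndim(timestamps) == 0 and not isinstance(
        timestamps, (list, tuple, np.ndarray, pd.Series, pd.DatetimeIndex)
    )
    idx = _as_datetimeindex(timestamps) - pd.Timedelta(hours=utc_offset_hours)
    _check_year_range(idx.year.to_numpy())
    T = (_julian_day(idx) - 2451545.0) / 36525.0
    rad = np.deg2rad
    # mean elongation, sun anomaly, moon anomaly (Meeus-style low precision)
    D = rad(297.8501921 + 445267.1114034 * T)
    M = rad(357.5291092 + 35999.0502909 * T)
    Mp = rad(134.9633964 + 477198.8675055 * T)
    phase_deg = (
        180.0
        - np.rad2deg(D) % 360.0
        - 6.289 * np.sin(Mp)
        + 2.100 * np.sin(M)
        - 1.274 * np.sin(2.0 * D - Mp)
        - 0.658 * np.sin(2.0 * D)
        - 0.214 * np.sin(2.0 * Mp)
        - 0.110 * np.sin(D)
    )
    frac = (1.0 + np.cos(rad(phase_deg))) / 2.0
    frac = np.clip(frac, 0.0, 1.0)
    if scalar:
        return float(frac[0])
    return frac
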