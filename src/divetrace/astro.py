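"""Solar and lunar timekeeping primitives.

Sunrise/sunset use the NOAA solar-position closed forms (fractional-year
Fourier series for the equation of time and solar declination).  Accuracy
is a couple of minutes, which is ample for classifying records into ±1 h
diel windows.  Lunar phase uses a mean synodic-month clock anchored at the
new moon of 2000-01-06 18:14 UTC; the mean clock drifts less than ±0.8 d
from the true phase, small against the 7.38 d phase windows used here.
"""

from __future__ import annotations

import datetime as dt
import math

from .errors import DivetraceError

SYNODIC_MONTH_DAYS = 29.530588853
#: reference new moon (J2000 era), UTC
NEW_MOON_EPOCH = dt.datetime(2000, 1, 6, 18, 14, tzinfo=dt.timezone.utc)

LUNAR_PHASES = ("new", "first_quarter", "full", "last_quarter")
DIEL_PERIODS = ("dawn", "day", "dusk", "night")


def _solar_coeffs(date: dt.date, hour_utc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    doy = date.timetuple().tm_yday
    leap = 366 if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0) else 365
    g = 2.0 * math.pi / leap * (doy - 1 + (hour_utc - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return eqtime, decl


def sun_events_utc(
    date: dt.date, lat: float, lon: float, zenith_deg: float = 90.0
) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset (UTC datetimes) for ``date`` at (lat, lon).

    ``lon`` positive east.  ``zenith_deg`` is the solar zenith angle that
    defines the event; 90.0 is the geometric horizon crossing, 90.833
    the conventional refraction-corrected value.

    Raises
    ------
    DivetraceError
        for polar latitudes (|lat| > 66°) where the day/night partition
        used here is not defined year-round.
    """
    if abs(lat) > 66.0:
        raise DivetraceError(f"polar latitude unsupported: {lat}")
    eqtime, decl = _solar_coeffs(date, 12.0)
    lat_r = math.radians(lat)
    cos_ha = (
        math.cos(math.radians(zenith_deg)) / (math.cos(lat_r) * math.cos(decl))
        - math.tan(lat_r) * math.tan(decl)
    )
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha_deg = math.degrees(math.acos(cos_ha))
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqtime
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    return (
        base + dt.timedelta(minutes=sunrise_min),
        base + dt.timedelta(minutes=sunset_min),
    )


def lunar_age_days(when: dt.date | dt.datetime) -> float:
    """Days since the preceding mean new moon, in [0, synodic month)."""
    if isinstance(when, dt.datetime):
        if when.tzinfo is None:
            when = when.replace(tzinfo=dt.timezone.utc)
    else:
        when = dt.datetime(when.year, when.month, when.day, 12, tzinfo=dt.timezone.utc)
    delta = (when - NEW_MOON_EPOCH).total_seconds() / 86400.0
    return delta % SYNODIC_MONTH_DAYS


def lunar_phase(when: dt.date | dt.datetime) -> str:
    """Quarter-phase label for a date.

    The synodic month is partitioned into four equal windows centred on
    the principal phases (new, first quarter, full, last quarter), so
    each date maps to exactly one label.
    """
    age = lunar_age_days(when)
    quarter = SYNODIC_MONTH_DAYS / 4.0
    idx = int(math.floor((age + quarter / 2.0) / quarter)) % 4
    return LUNAR_PHASES[idx]
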