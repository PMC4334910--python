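"""Solar event times and daily-period assignment.

Computes per-date sunrise/sunset and civil/nautical twilight boundaries for a
site using the NOAA solar-position equations (the "solar calculation
spreadsheet" formulation: geometric mean longitude/anomaly, equation of
center, apparent longitude, obliquity with nutation correction, equation of
time, and an hour-angle inversion at the event zenith).  Standard zeniths are
used: 90.833 deg for rise/set (refraction + solar radius), 96 deg for civil
twilight and 102 deg for nautical twilight.

Every 24-hour local day is partitioned into six periods bounded by those
events: day (sunrise to sunset), evening twilight (sunset to end of civil
twilight), evening nautical (end of civil to end of nautical twilight), night
(end of evening nautical to start of morning nautical twilight), morning
nautical, and morning twilight (start of civil twilight to sunrise).  All
intervals are half-open [start, end), so a sample whose timestamp equals
sunrise belongs to the day period.

All timestamps are naive local *standard* time with a fixed UTC offset (no
daylight saving), the usual biologging convention; the study default is
UTC-8 for a site near 50.6N, 122.5W.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, time, timedelta

import pandas as pd

ZENITH_RISE_SET = 90.833
ZENITH_CIVIL = 96.0
ZENITH_NAUTICAL = 102.0

#: The six daily periods, in clock order starting at midnight.
PERIODS = (
    "night",
    "morning_nautical",
    "morning_twilight",
    "day",
    "evening_twilight",
    "evening_nautical",
)

#: Pooling scheme: civil twilights count as day, nautical twilights as night.
POOLED_SCHEME = {
    "day": "day_pooled",
    "morning_twilight": "day_pooled",
    "evening_twilight": "day_pooled",
    "night": "night_pooled",
    "morning_nautical": "night_pooled",
    "evening_nautical": "night_pooled",
}


class NoSolarEventError(ValueError):
    """The sun does not cross the requested zenith on this date (polar case)."""


@dataclass(frozen=True)
class SolarDay:
    """Solar event times for one local date at one site.

    Event attributes are naive local-standard-time ``datetime`` values in
    clock order: ``nautical_dawn < civil_dawn < sunrise < sunset <
    civil_dusk < nautical_dusk`` (guaranteed for |lat| < 60).
    """

    date: _date
    latitude: float
    longitude: float
    tz_offset: float
    nautical_dawn: datetime
    civil_dawn: datetime
    sunrise: datetime
    sunset: datetime
    civil_dusk: datetime
    nautical_dusk: datetime

    @property
    def daylight_civil_hours(self) -> float:
        """Hours between morning and evening civil twilight."""
        return (self.civil_dusk - self.civil_dawn).total_seconds() / 3600.0

    def events(self) -> dict[str, datetime]:
        return {
            "nautical_dawn": self.nautical_dawn,
            "civil_dawn": self.civil_dawn,
            "sunrise": self.sunrise,
            "sunset": self.sunset,
            "civil_dusk": self.civil_dusk,
            "nautical_dusk": self.nautical_dusk,
        }


def _julian_day(d: _date) -> float:
    """Julian day number at 0h UT."""
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def _sun_eqtime_decl(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (degrees) at Julian
    century ``jc`` from J2000."""
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long))))
    vary = math.tan(math.radians(obliq / 2.0)) ** 2
    l0rad = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        vary * math.sin(2 * l0rad)
        - 2 * ecc * math.sin(mrad)
        + 4 * ecc * vary * math.sin(mrad) * math.cos(2 * l0rad)
        - 0.5 * vary * vary * math.sin(4 * l0rad)
        - 1.25 * ecc * ecc * math.sin(2 * mrad)
    )
    return eqtime, decl


def _hour_angle_deg(lat: float, decl: float, zenith: float) -> float:
    """Half the daylight arc (degrees) for the given event zenith.

    Raises :class:`NoSolarEventError` when the sun never reaches the zenith.
    """
    latr, declr, zr = map(math.radians, (lat, decl, zenith))
    cos_ha = (math.cos(zr) - math.sin(latr) * math.sin(declr)) / (math.cos(latr) * math.cos(declr))
    if cos_ha < -1.0 or cos_ha > 1.0:
        raise NoSolarEventError(
            f"sun does not cross zenith {zenith} deg at latitude {lat} on this date"
        )
    return math.degrees(math.acos(cos_ha))


def _event_minutes(d: _date, lat: float, lon: float, tz_offset: float, zenith: float,
                   rising: bool) -> float:
    """Local clock minutes past midnight of the requested event.

    One refinement pass re-evaluates the equation of time and declination at
    the first-pass event time, which brings the result within ~15 s of a full
    iterative solution.
    """
    jd = _julian_day(d)
    minutes = 720.0  # first guess: local noon
    for _ in range(2):
        jc = (jd + minutes / 1440.0 - tz_offset / 24.0 - 2451545.0) / 36525.0
        eqtime, decl = _sun_eqtime_decl(jc)
        ha = _hour_angle_deg(lat, decl, zenith)
        noon = 720.0 - 4.0 * lon - eqtime + tz_offset * 60.0
        minutes = noon - 4.0 * ha if rising else noon + 4.0 * ha
    return minutes


def solar_events(d: _date | datetime, lat: float, lon: float, tz_offset: float = -8.0) -> SolarDay:
    """Compute the six solar event times for one local date.

    Parameters
    ----------
    d
        Local calendar date (a datetime is truncated to its date).
    lat, lon
        Site coordinates in degrees; longitude negative west.  Latitudes
        poleward of 60 degrees are rejected: persistent-twilight cases are
        out of scope.
    tz_offset
        Fixed local-standard-time offset from UTC in hours (e.g. -8).
    """
    if isinstance(d, datetime):
        d = d.date()
    if abs(lat) >= 60.0:
        raise ValueError(f"latitude {lat} out of supported range (|lat| < 60)")

    def at(minutes: float) -> datetime:
        return datetime.combine(d, time(0)) + timedelta(minutes=minutes)

    ev = {}
    for name, zen, rising in (
        ("nautical_dawn", ZENITH_NAUTICAL, True),
        ("civil_dawn", ZENITH_CIVIL, True),
        ("sunrise", ZENITH_RISE_SET, True),
        ("sunset", ZENITH_RISE_SET, False),
        ("civil_dusk", ZENITH_CIVIL, False),
        ("nautical_dusk", ZENITH_NAUTICAL, False),
    ):
        ev[name] = at(_event_minutes(d, lat, lon, tz_offset, zen, rising))
    return SolarDay(date=d, latitude=lat, longitude=lon, tz_offset=tz_offset, **ev)


def assign_period(timestamp: datetime, solar_day: SolarDay) -> str:
    """Map a timestamp on ``solar_day``'s date to one of the six periods.

    Intervals are half-open [start, end); times before nautical dawn or at or
    after nautical dusk are night (night wraps across midnight).
    """
    timestamp = pd.Timestamp(timestamp).to_pydatetime()
    if timestamp.date() != solar_day.date:
        raise ValueError(
            f"timestamp {timestamp} is not on solar day {solar_day.date}"
        )
    s = solar_day
    if timestamp < s.nautical_dawn:
        return "night"
    if timestamp < s.civil_dawn:
        return "morning_nautical"
    if timestamp < s.sunrise:
        return "morning_twilight"
    if timestamp < s.sunset:
        return "day"
    if timestamp < s.civil_dusk:
        return "evening_twilight"
    if timestamp < s.nautical_dusk:
        return "evening_nautical"
    return "night"


def pooled_period(period: str, scheme: str = "civil_day") -> str:
    """Pool the six periods into day/night.

    The single supported scheme, ``"civil_day"``, pools the civil twilights
    with day and the nautical twilights with night.
    """
    if scheme != "civil_day":
        raise ValueError(f"unknown pooling scheme: {scheme!r}")
    try:
        return POOLED_SCHEME[period]
    except KeyError:
        raise ValueError(f"unknown daily period: {period!r}") from None


def annotate_periods(samples: pd.DataFrame, lat: float, lon: float,
                     tz_offset: float = -8.0,
                     timestamp_col: str = "timestamp") -> pd.DataFrame:
    """Add ``period``, ``pooled``, and ``daylight_civil_hours`` columns.

    Solar events are computed once per unique date, then each sample is
    assigned by its (5-minute) start timestamp.
    """
    out = samples.copy()
    ts = pd.to_datetime(out[timestamp_col])
    dates = ts.dt.normalize()
    period = pd.Series(index=out.index, dtype=object)
    daylight = pd.Series(index=out.index, dtype=float)
    for day, idx in dates.groupby(dates).groups.items():
        sd = solar_events(day.date(), lat, lon, tz_offset)
        period.loc[idx] = [assign_period(t, sd) for t in ts.loc[idx]]
        daylight.loc[idx] = sd.daylight_civil_hours
    out["period"] = period
    out["pooled"] = period.map(POOLED_SCHEME)
    out["daylight_civil_hours"] = daylight
    return out


def daylight_table(start: _date, end: _date, lat: float, lon: float,
                   tz_offset: float = -8.0) -> pd.DataFrame:
    """Per-date civil daylight hours over [start, end] inclusive."""
    rows = []
    d = start
    while d <= end:
        sd = solar_events(d, lat, lon, tz_offset)
        rows.append({"date": d, "daylight_civil_hours": sd.daylight_civil_hours})
        d = d + timedelta(days=1)
    return pd.DataFrame(rows)
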