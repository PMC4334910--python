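"""Independent solar ephemeris oracle for cross-checking ``solar_time``.

Deliberately implemented by a different route than the package: solar
apparent longitude by the classical low-accuracy series (Meeus, *Astronomical
Algorithms*, solar coordinates chapter), converted to right ascension and
declination, with the local hour angle obtained from Greenwich mean sidereal
time rather than from an equation-of-time expression.  Event times are found
by bisection on the geometric altitude crossing (-0.833 deg for rise/set,
-6 deg civil, -12 deg nautical), not by the closed-form hour-angle inversion
the package uses.  Agreement of the two routes to well under a minute is the
test's evidence of correctness.

Used at test-collection time only; also used once to generate the frozen
fixture ``tests/data/solar_oracle_2006_synthetic.csv``.
"""

from __future__ import annotations

import math
from datetime import date as _date
from datetime import datetime, time, timedelta


def _jd(dt_utc: datetime) -> float:
    y, m = dt_utc.year, dt_utc.month
    d = dt_utc.day + (dt_utc.hour + dt_utc.minute / 60.0 + dt_utc.second / 3600.0) / 24.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _sun_ra_dec(jd: float) -> tuple[float, float]:
    """Apparent right ascension and declination of the sun (degrees)."""
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + 36000.76983 * t + 0.0003032 * t * t) % 360.0
    m = math.radians(357.52911 + 35999.05029 * t - 0.0001537 * t * t)
    c = (
        (1.914602 - 0.004817 * t - 0.000014 * t * t) * math.sin(m)
        + (0.019993 - 0.000101 * t) * math.sin(2 * m)
        + 0.000289 * math.sin(3 * m)
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * t)
    lam = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + 26.0 / 60.0 + 21.448 / 3600.0 - (46.8150 * t + 0.00059 * t * t - 0.001813 * t ** 3) / 3600.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    ra = math.degrees(math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))) % 360.0
    dec = math.degrees(math.asin(math.sin(eps) * math.sin(lam)))
    return ra, dec


def _gmst_deg(jd: float) -> float:
    t = (jd - 2451545.0) / 36525.0
    gmst = 280.46061837 + 360.98564736629 * (jd - 2451545.0) + 0.000387933 * t * t - t ** 3 / 38710000.0
    return gmst % 360.0


def sun_altitude(dt_local: datetime, lat: float, lon: float, tz_offset: float) -> float:
    """Geometric solar altitude (degrees) at a naive local-standard time."""
    jd = _jd(dt_local - timedelta(hours=tz_offset))
    ra, dec = _sun_ra_dec(jd)
    lst = (_gmst_deg(jd) + lon) % 360.0
    ha = math.radians((lst - ra + 540.0) % 360.0 - 180.0)
    latr, decr = math.radians(lat), math.radians(dec)
    sin_h = math.sin(latr) * math.sin(decr) + math.cos(latr) * math.cos(decr) * math.cos(ha)
    return math.degrees(math.asin(sin_h))


def _bisect_crossing(d: _date, lat: float, lon: float, tz_offset: float,
                     target_alt: float, rising: bool) -> datetime:
    """Bisection for the altitude crossing in the morning or evening half-day."""
    midnight = datetime.combine(d, time(0))
    lo, hi = (0.0, 12.0) if rising else (12.0, 24.0)

    def f(hours: float) -> float:
        return sun_altitude(midnight + timedelta(hours=hours), lat, lon, tz_offset) - target_alt

    flo, fhi = f(lo), f(hi)
    if (flo < 0) == (fhi < 0):
        raise ValueError(f"no altitude crossing of {target_alt} on {d}")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if (f(mid) < 0) == (flo < 0):
            lo, flo = mid, f(mid)
        else:
            hi = mid
    return midnight + timedelta(hours=0.5 * (lo + hi))


def oracle_events(d: _date, lat: float, lon: float, tz_offset: float) -> dict[str, datetime]:
    """The six solar events for one local date, independent route."""
    return {
        "nautical_dawn": _bisect_crossing(d, lat, lon, tz_offset, -12.0, True),
        "civil_dawn": _bisect_crossing(d, lat, lon, tz_offset, -6.0, True),
        "sunrise": _bisect_crossing(d, lat, lon, tz_offset, -0.833, True),
        "sunset": _bisect_crossing(d, lat, lon, tz_offset, -0.833, False),
        "civil_dusk": _bisect_crossing(d, lat, lon, tz_offset, -6.0, False),
        "nautical_dusk": _bisect_crossing(d, lat, lon, tz_offset, -12.0, False),
    }
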