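"""Ephemeris-style solar oracle: the NOAA solar-calculator formulation
(Julian-century polynomial for the sun's geometric position), implemented
from the published equations, independent of the package under test."""

import math

def _noaa_declination(doy: int, year: int = 2022) -> float:
    import datetime as dt

    date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
    jd = date.toordinal() + 1721424.5 + 0.5  # noon
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    c = (
        math.sin(math.radians(m)) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(math.radians(2 * m)) * (0.019993 - 0.000101 * t)
        + math.sin(math.radians(3 * m)) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    e0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    e_corr = e0 + 0.00256 * math.cos(math.radians(omega))
    return math.degrees(
        math.asin(math.sin(math.radians(e_corr)) * math.sin(math.radians(app_long)))
    )


def _oracle_elevation(lat: float, doy: int, solar_hour: float) -> float:
    decl = math.radians(_noaa_declination(doy))
    phi = math.radians(lat)
    h = math.radians(15.0 * (solar_hour - 12.0))
    sin_e = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(h)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_e))))
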