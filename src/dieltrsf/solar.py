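"""Solar geometry on the absolute (UTC) timeline.

Implements an ephemeris-grade solar position algorithm of the NOAA/Meeus
class: apparent solar longitude from the mean anomaly series, obliquity with
nutation correction, giving declination and the equation of time. Event
times (solar noon, solar nadir, altitude crossings such as astronomical
twilight) are solved iteratively from the hour angle. Stated accuracy of the
underlying series is well under 1 minute for years 1900-2100, which is
inside the ~2 minute spread among common implementations of sunrise-class
events (refraction assumptions dominate).

All instants are timezone-aware UTC datetimes; all internal arithmetic uses
Unix seconds, so daylight-saving transitions never enter the computation.
"""

from __future__ import annotations

import math
from datetime import datetime, timezone

__all__ = [
    "TwilightUndefinedError",
    "solar_declination_eot",
    "solar_altitude",
    "solar_noon_near",
    "solar_nadir_near",
    "altitude_crossing",
]

_J2000_UNIX = 946728000.0  # 2000-01-01 12:00:00 UTC


class TwilightUndefinedError(ValueError):
    """The sun never crosses the requested altitude on this date/latitude.

    Raised e.g. when astronomical twilight does not exist (midsummer at
    high latitude) or the sun never rises. The message names the missing
    event so callers can fail loudly rather than mis-categorize.
    """

    def __init__(self, event: str, when: datetime, latitude: float):
        self.event = event
        self.when = when
        self.latitude = latitude
        super().__init__(
            f"solar event {event!r} undefined near {when.isoformat()} "
            f"at latitude {latitude:.3f} deg"
        )


def _to_unix(t: datetime) -> float:
    if t.tzinfo is None:
        raise ValueError("naive datetime; an explicit timezone is required")
    return t.timestamp()


def _from_unix(s: float) -> datetime:
    return datetime.fromtimestamp(s, tz=timezone.utc)


def solar_declination_eot(t_unix: float) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes) at a Unix time."""
    T = (t_unix - _J2000_UNIX) / (36525.0 * 86400.0)
    # geometric mean longitude and anomaly of the sun (degrees)
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = math.radians(M)
    C = (
        (1.914602 - T * (0.004817 + 0.000014 * T)) * math.sin(Mr)
        + (0.019993 - 0.000101 * T) * math.sin(2 * Mr)
        + 0.000289 * math.sin(3 * Mr)
    )
    true_long = L0 + C
    omega = math.radians(125.04 - 1934.136 * T)
    # apparent longitude (nutation + aberration)
    lam = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    dec = math.asin(math.sin(eps) * math.sin(lam))

    y = math.tan(eps / 2.0) ** 2
    L0r = math.radians(L0)
    eot_rad = (
        y * math.sin(2 * L0r)
        - 2 * e * math.sin(Mr)
        + 4 * e * y * math.sin(Mr) * math.cos(2 * L0r)
        - 0.5 * y * y * math.sin(4 * L0r)
        - 1.25 * e * e * math.sin(2 * Mr)
    )
    eot_min = 4.0 * math.degrees(eot_rad)
    return dec, eot_min


def _hour_angle_deg(t_unix: float, longitude: float) -> float:
    """True solar hour angle in degrees, wrapped to [-180, 180)."""
    _, eot = solar_declination_eot(t_unix)
    utc_min = (t_unix % 86400.0) / 60.0
    tst = utc_min + eot + 4.0 * longitude  # true solar time, minutes
    ha = tst / 4.0 - 180.0
    return (ha + 180.0) % 360.0 - 180.0


def solar_altitude(t: datetime, latitude: float, longitude: float) -> float:
    """Altitude of the sun's center in degrees (no refraction applied)."""
    s = _to_unix(t)
    dec, _ = solar_declination_eot(s)
    ha = math.radians(_hour_angle_deg(s, longitude))
    lat = math.radians(latitude)
    sin_alt = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(ha)
    return math.degrees(math.asin(sin_alt))


def solar_noon_near(t_guess: datetime, longitude: float) -> datetime:
    """Solar noon (hour angle 0) closest to ``t_guess``."""
    s = _to_unix(t_guess)
    for _ in range(5):
        s -= _hour_angle_deg(s, longitude) * 240.0  # 4 min per degree
    return _from_unix(s)


def solar_nadir_near(t_guess: datetime, longitude: float) -> datetime:
    """Solar nadir / solar midnight (hour angle 180) closest to ``t_guess``."""
    s = _to_unix(t_guess)
    for _ in range(5):
        ha = _hour_angle_deg(s, longitude)
        delta = (ha - 180.0 + 180.0) % 360.0 - 180.0
        s -= delta * 240.0
    return _from_unix(s)


def altitude_crossing(
    noon: datetime,
    latitude: float,
    longitude: float,
    altitude_deg: float,
    morning: bool,
    event: str = "altitude crossing",
) -> datetime:
    """Instant the sun's center crosses ``altitude_deg`` on one side of a solar noon.

    ``morning=True`` solves the ascending crossing before ``noon``;
    ``morning=False`` the descending crossing after it. Raises
    :class:`TwilightUndefinedError` when no such crossing exists.
    """
    noon_s = _to_unix(noon)
    lat = math.radians(latitude)
    h0 = math.radians(altitude_deg)
    t = noon_s
    for _ in range(4):
        dec, _ = solar_declination_eot(t)
        cos_h = (math.sin(h0) - math.sin(lat) * math.sin(dec)) / (
            math.cos(lat) * math.cos(dec)
        )
        if cos_h < -1.0 or cos_h > 1.0:
            raise TwilightUndefinedError(event, _from_unix(noon_s), latitude)
        H = math.degrees(math.acos(cos_h))  # degrees from noon
        t = noon_s - H * 240.0 if morning else noon_s + H * 240.0
    return _from_unix(t)
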