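"""Diel-category schedules: dawn / day / dusk / night / deep night.

A diel cycle runs from one solar noon to the next, so the deep-night window
(solar nadir +/- 1 h) is never split across cycles. Category boundaries are
sun-altitude events:

* dawn: morning astronomical twilight start (sun center -18 deg) to the
  moment the bottom edge of the sun touches the horizon (center -0.3 deg);
* day: from the end of dawn to the evening -0.3 deg crossing;
* dusk: evening -0.3 deg crossing to the end of evening astronomical
  twilight (-18 deg), when it is dark enough for astronomical observations;
* deep night: 1 h either side of the solar nadir;
* night: the remaining dark intervals.

Intervals are half-open [start, end): an instant exactly on a boundary
belongs to the later category. Availability alpha[k] is the total hours the
cycle offers in category k; by construction alpha["deep_night"] == 2.0 and
the five alphas sum to the cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, datetime, timedelta, timezone
from zoneinfo import ZoneInfo

from .solar import (
    TwilightUndefinedError,
    altitude_crossing,
    solar_nadir_near,
    solar_noon_near,
)

__all__ = [
    "CATEGORIES",
    "GeoPoint",
    "DielSchedule",
    "OutOfCycleError",
    "compute_schedule",
    "schedule_for_instant",
    "categorize_timestamp",
]

#: category order used throughout; index 0 ("day") is the model's reference
CATEGORIES = ("day", "dawn", "dusk", "night", "deep_night")

#: sun-center altitude when its bottom edge touches the horizon
#: (refraction + semidiameter convention of the suncalc event set)
SUN_EDGE_ALTITUDE = -0.3
#: astronomical twilight threshold
ASTRO_ALTITUDE = -18.0

DEEP_NIGHT_HALF_WIDTH = timedelta(hours=1)


class OutOfCycleError(ValueError):
    """Timestamp lies outside the schedule's solar-noon-to-solar-noon cycle."""


@dataclass(frozen=True)
class GeoPoint:
    """A camera-station location: latitude/longitude in decimal degrees plus
    an IANA timezone name used only when parsing local civil timestamps."""

    latitude: float
    longitude: float
    tz_name: str = "UTC"

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        ZoneInfo(self.tz_name)  # raises for unknown identifiers

    @property
    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.tz_name)


@dataclass(frozen=True)
class DielSchedule:
    """The five diel-category boundaries for one solar-noon-to-solar-noon cycle."""

    cycle_start: datetime
    cycle_end: datetime
    nadir: datetime
    boundaries: tuple[tuple[str, datetime, datetime], ...]
    alpha: dict[str, float] = field(compare=False)

    @property
    def cycle_hours(self) -> float:
        return (self.cycle_end - self.cycle_start).total_seconds() / 3600.0

    def alpha_vector(self) -> list[float]:
        """Availability hours ordered as :data:`CATEGORIES`."""
        return [self.alpha[c] for c in CATEGORIES]


def compute_schedule(date: _date, location: GeoPoint) -> DielSchedule:
    """Diel schedule for the cycle opening at ``date``'s solar noon.

    Raises :class:`~dieltrsf.solar.TwilightUndefinedError` where the sun
    never reaches -18 deg (no astronomical twilight) or never clears the
    horizon, rather than silently falling back to another twilight scheme.
    """
    if not 1900 <= date.year <= 2100:
        raise ValueError(f"date {date} outside supported years 1900-2100")
    lat, lon = location.latitude, location.longitude
    guess = datetime(date.year, date.month, date.day, 12, tzinfo=timezone.utc) - timedelta(
        hours=lon / 15.0
    )
    noon0 = solar_noon_near(guess, lon)
    noon1 = solar_noon_near(noon0 + timedelta(hours=24), lon)
    nadir = solar_nadir_near(noon0 + timedelta(hours=12), lon)

    sunset_edge = altitude_crossing(
        noon0, lat, lon, SUN_EDGE_ALTITUDE, morning=False, event="sunset (bottom edge)"
    )
    eve_astro = altitude_crossing(
        noon0, lat, lon, ASTRO_ALTITUDE, morning=False, event="evening astronomical twilight end"
    )
    sunrise_edge = altitude_crossing(
        noon1, lat, lon, SUN_EDGE_ALTITUDE, morning=True, event="sunrise (bottom edge)"
    )
    morn_astro = altitude_crossing(
        noon1, lat, lon, ASTRO_ALTITUDE, morning=True, event="morning astronomical twilight start"
    )

    deep_start = nadir - DEEP_NIGHT_HALF_WIDTH
    deep_end = nadir + DEEP_NIGHT_HALF_WIDTH
    # Marginal short nights (|lat| ~ 47-50 near the June solstice): the -18 deg
    # crossing can fall inside the deep-night window; clip so the categories
    # still partition the cycle (night length 0 there).
    eve_astro = min(eve_astro, deep_start)
    morn_astro = max(morn_astro, deep_end)
    sunset_edge = min(sunset_edge, eve_astro)
    sunrise_edge = max(sunrise_edge, morn_astro)

    boundaries = (
        ("day", noon0, sunset_edge),
        ("dusk", sunset_edge, eve_astro),
        ("night", eve_astro, deep_start),
        ("deep_night", deep_start, deep_end),
        ("night", deep_end, morn_astro),
        ("dawn", morn_astro, sunrise_edge),
        ("day", sunrise_edge, noon1),
    )
    alpha = {c: 0.0 for c in CATEGORIES}
    for cat, start, end in boundaries:
        alpha[cat] += (end - start).total_seconds() / 3600.0
    return DielSchedule(
        cycle_start=noon0, cycle_end=noon1, nadir=nadir, boundaries=boundaries, alpha=alpha
    )


def schedule_for_instant(t: datetime, location: GeoPoint) -> DielSchedule:
    """The schedule of the solar cycle containing ``t`` (night never split)."""
    if t.tzinfo is None:
        raise ValueError("naive datetime; an explicit timezone is required")
    t_utc = t.astimezone(timezone.utc)
    day = t_utc.date()
    for _ in range(4):
        sched = compute_schedule(day, location)
        if t_utc < sched.cycle_start:
            day -= timedelta(days=1)
        elif t_utc >= sched.cycle_end:
            day += timedelta(days=1)
        else:
            return sched
    raise OutOfCycleError(  # pragma: no cover
        f"could not locate solar cycle containing {t.isoformat()}"
    )


def categorize_timestamp(t: datetime, schedule: DielSchedule) -> str:
    """Category of the half-open boundary interval containing ``t``."""
    if t.tzinfo is None:
        raise ValueError("naive datetime; an explicit timezone is required")
    t_utc = t.astimezone(timezone.utc)
    if not (schedule.cycle_start <= t_utc < schedule.cycle_end):
        raise OutOfCycleError(
            f"{t.isoformat()} outside cycle [{schedule.cycle_start.isoformat()}, "
            f"{schedule.cycle_end.isoformat()})"
        )
    for cat, start, end in schedule.boundaries:
        if start <= t_utc < end:
            return cat
    raise OutOfCycleError(f"no interval contains {t.isoformat()}")  # pragma: no cover
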