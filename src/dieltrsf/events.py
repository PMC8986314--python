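"""Photo records -> deduplicated detection events with diel categories.

A detection event is all photos of one species at one camera station whose
successive gaps stay within a grouping window (15 min by default). The
chain rule is the default (a photo opens a new event iff its gap to the
previous photo exceeds the window); a fixed-anchor variant measuring gaps
from the event's first photo is available for sensitivity checks.
"""

from __future__ import annotations

import logging
import math
from datetime import timedelta

import numpy as np
import pandas as pd

from .diel import CATEGORIES, GeoPoint, categorize_timestamp, schedule_for_instant

__all__ = [
    "dedupe_events",
    "compute_trap_nights",
    "assign_categories",
    "ALPHA_COLUMNS",
]

logger = logging.getLogger(__name__)

ALPHA_COLUMNS = [f"alpha_{c}" for c in CATEGORIES]


def _parse_timestamps(photos: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse the timestamp column to UTC; split off unparseable rows."""
    ts = pd.to_datetime(photos["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        rejected = photos.loc[bad].copy()
        rejected["reject_reason"] = "unparseable timestamp"
        logger.warning("rejected %d photo records with unparseable timestamps", bad.sum())
    else:
        rejected = photos.iloc[0:0].copy()
        rejected["reject_reason"] = pd.Series(dtype=object)
    out = photos.loc[~bad].copy()
    out["timestamp"] = ts[~bad]
    return out, rejected


def dedupe_events(
    photos: pd.DataFrame,
    window_minutes: float = 15.0,
    rule: str = "chain",
    return_rejected: bool = False,
):
    """Collapse photo bursts into detection events.

    Parameters
    ----------
    photos : DataFrame with columns station_id, species, timestamp
        Timestamps ISO-8601 with explicit offset (or already tz-aware).
    window_minutes : grouping window, default 15.
    rule : "chain" (gap to previous photo) or "anchor" (gap to the event's
        first photo).
    return_rejected : also return the rows dropped for unparseable
        timestamps, with a reject_reason column.

    Returns a DataFrame of event stubs (event_id, station_id, species,
    timestamp of the first photo, n_photos), deterministically sorted.
    """
    if rule not in ("chain", "anchor"):
        raise ValueError(f"unknown grouping rule {rule!r}")
    cols = ["station_id", "species", "timestamp"]
    missing = [c for c in cols if c not in photos.columns]
    if missing:
        raise ValueError(f"photos table missing columns: {missing}")
    if len(photos) == 0:
        empty = pd.DataFrame(
            columns=["event_id", "station_id", "species", "timestamp", "n_photos"]
        )
        return (empty, photos.copy()) if return_rejected else empty

    ok, rejected = _parse_timestamps(photos[cols])
    ok = ok.sort_values(cols, kind="mergesort").reset_index(drop=True)
    window = pd.Timedelta(minutes=window_minutes)

    new_stream = (ok["station_id"] != ok["station_id"].shift()) | (
        ok["species"] != ok["species"].shift()
    )
    if rule == "chain":
        gap = ok["timestamp"].diff()
        new_event = new_stream | (gap > window)
        event_idx = new_event.cumsum()
    else:  # anchor: gap measured from the event's first photo
        event_idx = np.empty(len(ok), dtype=np.int64)
        eid = 0
        anchor = None
        for i, (fresh, t) in enumerate(zip(new_stream.to_numpy(), ok["timestamp"])):
            if fresh or t - anchor > window:
                eid += 1
                anchor = t
            event_idx[i] = eid
        event_idx = pd.Series(event_idx, index=ok.index)

    events = (
        ok.groupby(event_idx)
        .agg(
            station_id=("station_id", "first"),
            species=("species", "first"),
            timestamp=("timestamp", "first"),
            n_photos=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    events.insert(0, "event_id", np.arange(len(events)))
    return (events, rejected) if return_rejected else events


def compute_trap_nights(deployments: pd.DataFrame) -> int:
    """Total sampling effort in trap nights.

    Each (station, start, end) interval contributes floor(interval length in
    nights); intervals at one station must not overlap. A station active
    from Jan 1 to Jan 11 contributes 10 trap nights.
    """
    if len(deployments) == 0:
        return 0
    dep = deployments.copy()
    dep["start"] = pd.to_datetime(dep["start"])
    dep["end"] = pd.to_datetime(dep["end"])
    if (dep["end"] < dep["start"]).any():
        bad = dep.loc[dep["end"] < dep["start"], "station_id"].tolist()
        raise ValueError(f"deployment end before start at stations {bad}")
    for station, grp in dep.groupby("station_id"):
        g = grp.sort_values("start")
        if (g["start"].iloc[1:].to_numpy() < g["end"].iloc[:-1].to_numpy()).any():
            raise ValueError(f"overlapping deployment intervals at station {station!r}")
    nights = ((dep["end"] - dep["start"]) / timedelta(days=1)).apply(math.floor)
    return int(nights.sum())


def assign_categories(
    stubs: pd.DataFrame,
    sites: pd.DataFrame,
    temperatures: pd.DataFrame | None = None,
    drop_missing_temperature: bool = False,
) -> pd.DataFrame:
    """Attach diel category, availability vector, and daily mean temperature.

    Parameters
    ----------
    stubs : event stubs from :func:`dedupe_events`.
    sites : DataFrame station_id, site_id, city_id, lat, lon, tz.
    temperatures : optional DataFrame city_id, date, tavg_c; the event's
        temperature is the daily mean of its local civil date and city.
    drop_missing_temperature : drop (rather than flag with NaN) events whose
        date is absent from the temperature series.

    Events keep their stub columns and gain city_id, category,
    alpha_day..alpha_deep_night, and daily_mean_temperature (if a
    temperature table is given). Availability depends only on the site and
    the solar cycle, so schedules are cached per (station, cycle).
    """
    known = set(sites["station_id"])
    unknown = sorted(set(stubs["station_id"]) - known)
    if unknown:
        raise ValueError(f"no site coordinates for stations: {unknown}")

    site_map = sites.set_index("station_id")
    out = stubs.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)

    cache: dict[tuple, object] = {}
    categories = np.empty(len(out), dtype=object)
    alphas = np.empty((len(out), len(CATEGORIES)))
    city_ids = np.empty(len(out), dtype=object)
    site_ids = np.empty(len(out), dtype=object)
    for pos, row in enumerate(out.itertuples(index=False)):
        srow = site_map.loc[row.station_id]
        point = GeoPoint(float(srow["lat"]), float(srow["lon"]), str(srow.get("tz", "UTC")))
        t = row.timestamp.to_pydatetime()
        key = (row.station_id, t.date())
        sched = cache.get(key)
        if sched is None or not (sched.cycle_start <= t < sched.cycle_end):
            sched = schedule_for_instant(t, point)
            cache[(row.station_id, sched.cycle_start.date())] = sched
            cache[key] = sched
        categories[pos] = categorize_timestamp(t, sched)
        alphas[pos] = sched.alpha_vector()
        city_ids[pos] = srow["city_id"]
        site_ids[pos] = srow["site_id"] if "site_id" in site_map.columns else row.station_id
    out["site_id"] = site_ids
    out["city_id"] = city_ids
    out["category"] = categories
    for k, col in enumerate(ALPHA_COLUMNS):
        out[col] = alphas[:, k]

    if temperatures is not None:
        tz_by_station = site_map["tz"] if "tz" in site_map.columns else None
        local_dates = []
        for row in out.itertuples(index=False):
            tz = "UTC" if tz_by_station is None else str(tz_by_station.loc[row.station_id])
            local_dates.append(row.timestamp.tz_convert(tz).date())
        out["date"] = local_dates
        temp = temperatures.copy()
        temp["date"] = pd.to_datetime(temp["date"]).dt.date
        out = out.merge(
            temp.rename(columns={"tavg_c": "daily_mean_temperature"}),
            on=["city_id", "date"],
            how="left",
        )
        n_missing = out["daily_mean_temperature"].isna().sum()
        if n_missing:
            logger.warning(
                "%d events lack a daily temperature for their city/date", n_missing
            )
            if drop_missing_temperature:
                out = out.loc[out["daily_mean_temperature"].notna()].reset_index(drop=True)
    return out
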