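"""Independence filtering of camera-trap detection records.

A motion-triggered camera fires many images as one animal lingers; the
analysis unit is the *independent detection event*: consecutive images of the
same species at the same station belong to one event unless the gap to the
immediately preceding image strictly exceeds a threshold (30 minutes for
wildlife, 1 minute for humans, whose trail traffic is far denser). The gap is
chained from the previous *record*, not from the event's first record; an
``anchor="event_start"`` variant is available for comparison.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_detections",
    "filter_independent_events",
    "count_detections",
    "period_key",
]

REQUIRED_COLUMNS = ("station_id", "species", "timestamp")


def read_detections(path) -> pd.DataFrame:
    """Read a detections CSV, parsing timestamps and naming any bad row."""
    df = pd.read_csv(path, dtype={"station_id": str, "species": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detections file {path} missing columns: {missing}")
    parsed = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = parsed.isna() & df["timestamp"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {df['timestamp'].iloc[row]!r} in row {row} of {path}"
        )
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(f"missing timestamp in row {row} of {path}")
    df["timestamp"] = parsed
    return df


def filter_independent_events(
    records: pd.DataFrame,
    threshold_minutes: float,
    group_keys: Sequence[str] = ("station_id", "species"),
    anchor: str = "chain",
) -> pd.DataFrame:
    """Collapse detection records into independent events.

    Parameters
    ----------
    records : DataFrame
        Columns ``station_id``, ``species``, ``timestamp`` (datetime64).
    threshold_minutes : float
        A record starts a new event iff its gap to the reference record
        strictly exceeds this (a gap of exactly the threshold does *not*
        break an event).
    group_keys : sequence of str
        Grouping columns; default station x species.
    anchor : {"chain", "event_start"}
        "chain" measures the gap from the immediately preceding record;
        "event_start" measures it from the current event's first record.

    Returns
    -------
    DataFrame
        One row per event: group keys, ``start_timestamp``, ``n_records``,
        sorted by group then start time.
    """
    if threshold_minutes <= 0:
        raise ValueError("threshold_minutes must be > 0")
    if anchor not in ("chain", "event_start"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if records.empty:
        return pd.DataFrame(
            columns=list(group_keys) + ["start_timestamp", "n_records"]
        )
    if not pd.api.types.is_datetime64_any_dtype(records["timestamp"]):
        raise TypeError("timestamp column must be datetime64; use read_detections")

    df = records.sort_values(list(group_keys) + ["timestamp"], kind="mergesort")
    threshold = pd.Timedelta(minutes=threshold_minutes)

    if anchor == "chain":
        gaps = df.groupby(list(group_keys), sort=False)["timestamp"].diff()
        new_event = gaps.isna() | (gaps > threshold)
        event_id = new_event.cumsum()
        out = (
            df.assign(_event=event_id)
            .groupby(list(group_keys) + ["_event"], sort=False)
            .agg(start_timestamp=("timestamp", "first"), n_records=("timestamp", "size"))
            .reset_index()
            .drop(columns="_event")
        )
    else:
        rows = []
        for keys, grp in df.groupby(list(group_keys), sort=False):
            times = grp["timestamp"].to_numpy()
            start = times[0]
            n = 0
            for t in times:
                if n and (t - start) > threshold.to_numpy():
                    rows.append((*_tup(keys), start, n))
                    start, n = t, 0
                n += 1
            rows.append((*_tup(keys), start, n))
        out = pd.DataFrame(rows, columns=list(group_keys) + ["start_timestamp", "n_records"])

    return out.sort_values(list(group_keys) + ["start_timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def _tup(keys):
    return keys if isinstance(keys, tuple) else (keys,)


def period_key(timestamps, scale: str) -> pd.Series:
    """Map timestamps to a calendar-day, ISO-week, or calendar-month key.

    Weeks follow ISO-8601 (Monday-Sunday); months are calendar months.
    """
    ts = pd.Series(pd.to_datetime(timestamps))
    if scale == "day":
        return ts.dt.strftime("%Y-%m-%d")
    if scale == "week":
        iso = ts.dt.isocalendar()
        return iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    if scale == "month":
        return ts.dt.strftime("%Y-%m")
    raise ValueError(f"unknown scale {scale!r}; expected day/week/month")


def count_detections(events: pd.DataFrame, station_id, interval) -> int:
    """Number of events at one station whose start falls in a calendar interval.

    ``interval`` is a ``(scale, key)`` pair where ``scale`` is ``"day"``,
    ``"week"`` or ``"month"`` and ``key`` matches :func:`period_key` output
    (e.g. ``("day", "2019-06-01")``, ``("week", "2019-W23")``,
    ``("month", "2019-06")``); a bare date-like is treated as a day.
    """
    if events.empty:
        return 0
    if isinstance(interval, tuple):
        scale, key = interval
    else:
        scale, key = "day", pd.Timestamp(interval).strftime("%Y-%m-%d")
    at_station = events[events["station_id"] == station_id]
    if at_station.empty:
        return 0
    keys = period_key(at_station["start_timestamp"], scale)
    return int((keys == key).sum())
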