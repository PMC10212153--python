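"""Predictor construction: human presence rates, infrastructure geometry,
environmental attributes.

Human presence is measured at three temporal scales anchored on each wildlife
event: the human event count at that station on the same calendar day, and
the human event counts over the same ISO week / calendar month divided by the
number of days the camera was active in that period (detections per active
camera-day). A period in which the camera was never active yields a *missing*
rate, not zero — "no humans recorded" and "camera off" must not be conflated —
and the event is dropped from the model table with a logged count.

Infrastructure geometry is exact planar math on a local metric frame:
trail/road density is the total polyline length clipped to the closed 500 m
disk around the station divided by the disk area (m/m^2), computed by
analytic segment-circle intersection; distance to the urban-wildland boundary
is the minimum point-to-segment distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, Point
from shapely.geometry.base import BaseGeometry

from .astro import SolarContext, lunar_fraction, nocturnality
from .events import period_key

__all__ = [
    "HumanPresence",
    "line_density_in_buffer",
    "distance_to_boundary",
    "human_presence_for_event",
    "human_presence_table",
    "station_covariates",
    "assemble_model_table",
]

logger = logging.getLogger(__name__)

DEFAULT_BUFFER_RADIUS_M = 500.0

PREDICTOR_COLUMNS = (
    "daily_human_detections",
    "weekly_human_rate",
    "monthly_human_rate",
    "trail_density",
    "road_density",
    "dist_boundary",
    "lunar_fraction",
    "crown_closure",
)


@dataclass(frozen=True)
class HumanPresence:
    """Human-presence measures anchored on one wildlife event."""

    event_ref: object
    daily_count: int
    weekly_rate: Optional[float]
    monthly_rate: Optional[float]


# --- geometry --------------------------------------------------------------

def _iter_segments(lines) -> Iterable[np.ndarray]:
    """Yield (n, 2, 2) segment arrays from LineString/MultiLineString/lists."""
    if lines is None:
        return
    if isinstance(lines, BaseGeometry):
        if lines.is_empty:
            return
        geoms = lines.geoms if isinstance(lines, MultiLineString) else [lines]
        for geom in geoms:
            coords = np.asarray(geom.coords, dtype=float)[:, :2]
            if len(coords) >= 2:
                yield np.stack([coords[:-1], coords[1:]], axis=1)
    else:
        for item in lines:
            yield from _iter_segments(item)


def _clipped_length(segments: np.ndarray, center: np.ndarray, radius: float) -> float:
    """Total length of segments inside the closed disk, by quadratic roots."""
    p1 = segments[:, 0, :] - center
    d = segments[:, 1, :] - segments[:, 0, :]
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", p1, d)
    c = np.einsum("ij,ij->i", p1, p1) - radius * radius
    disc = b * b - 4.0 * a * c
    ok = (a > 0) & (disc > 0)
    if not ok.any():
        return 0.0
    sq = np.sqrt(disc[ok])
    t1 = (-b[ok] - sq) / (2.0 * a[ok])
    t2 = (-b[ok] + sq) / (2.0 * a[ok])
    lo = np.clip(t1, 0.0, 1.0)
    hi = np.clip(t2, 0.0, 1.0)
    return float(np.sum(np.sqrt(a[ok]) * np.maximum(0.0, hi - lo)))


def line_density_in_buffer(lines, station_xy, radius_m: float = DEFAULT_BUFFER_RADIUS_M) -> float:
    """Line length within the closed ``radius_m`` disk around the station,
    divided by the disk area (m/m^2).

    Exact segment-circle clipping; empty geometry gives density 0.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be > 0")
    center = np.asarray(
        station_xy.coords[0][:2] if isinstance(station_xy, Point) else station_xy,
        dtype=float,
    )
    total = 0.0
    for segs in _iter_segments(lines):
        total += _clipped_length(segs, center, radius_m)
    return total / (np.pi * radius_m * radius_m)


def distance_to_boundary(station_xy, boundary) -> float:
    """Minimum Euclidean distance from the station to the boundary polyline(s)."""
    if boundary is None or (isinstance(boundary, BaseGeometry) and boundary.is_empty):
        raise ValueError("boundary geometry is empty")
    point = station_xy if isinstance(station_xy, Point) else Point(*np.asarray(station_xy, dtype=float))
    if isinstance(boundary, BaseGeometry):
        return float(point.distance(boundary))
    dists = [point.distance(g) for g in boundary]
    if not dists:
        raise ValueError("boundary geometry is empty")
    return float(min(dists))


def station_covariates(
    stations: pd.DataFrame,
    trails,
    roads,
    boundary,
    radius_m: float = DEFAULT_BUFFER_RADIUS_M,
) -> pd.DataFrame:
    """Recompute geometric covariates for every station from line layers.

    Returns a copy of ``stations`` with ``trail_density``, ``road_density``
    and ``dist_boundary`` columns derived from the geometries.
    """
    out = stations.copy()
    xy = out[["x", "y"]].to_numpy(dtype=float)
    out["trail_density"] = [line_density_in_buffer(trails, p, radius_m) for p in xy]
    out["road_density"] = [line_density_in_buffer(roads, p, radius_m) for p in xy]
    out["dist_boundary"] = [distance_to_boundary(p, boundary) for p in xy]
    return out


# --- human presence --------------------------------------------------------

def _active_days_per_period(effort: pd.DataFrame, scale: str) -> pd.Series:
    """Active camera-days per station per period, indexed (station_id, key)."""
    active = effort[effort["active"].astype(bool)]
    keys = period_key(active["date"], scale)
    return active.assign(_key=keys).groupby(["station_id", "_key"]).size()


def _human_counts_per_period(human_events: pd.DataFrame, scale: str) -> pd.Series:
    if human_events.empty:
        return pd.Series(dtype=int)
    keys = period_key(human_events["start_timestamp"], scale)
    return human_events.assign(_key=keys).groupby(["station_id", "_key"]).size()


def human_presence_table(
    wildlife_events: pd.DataFrame,
    human_events: pd.DataFrame,
    effort: pd.DataFrame,
) -> pd.DataFrame:
    """Daily count and weekly/monthly rates for every wildlife event.

    Returns one row per input event with columns ``daily_human_detections``,
    ``weekly_human_rate``, ``monthly_human_rate``; rates are NaN where the
    camera had zero active days in that period.
    """
    known = set(effort["station_id"].unique())
    unknown = set(wildlife_events["station_id"].unique()) - known
    if unknown:
        raise ValueError(f"stations absent from effort log: {sorted(unknown)}")

    out = pd.DataFrame(index=wildlife_events.index)
    for scale, col in (
        ("day", "daily_human_detections"),
        ("week", "weekly_human_rate"),
        ("month", "monthly_human_rate"),
    ):
        counts = _human_counts_per_period(human_events, scale)
        keys = period_key(wildlife_events["start_timestamp"], scale)
        idx = pd.MultiIndex.from_arrays(
            [wildlife_events["station_id"].to_numpy(), keys.to_numpy()]
        )
        n_human = counts.reindex(idx).fillna(0).to_numpy(dtype=float)
        if scale == "day":
            out[col] = n_human
        else:
            active = _active_days_per_period(effort, scale)
            n_active = active.reindex(idx).to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[col] = np.where(np.isnan(n_active), np.nan, n_human / n_active)
    return out


def human_presence_for_event(event, human_events: pd.DataFrame, effort: pd.DataFrame) -> HumanPresence:
    """Human-presence measures for a single wildlife event (row with
    ``station_id`` and ``start_timestamp``)."""
    one = pd.DataFrame([{"station_id": event["station_id"], "start_timestamp": event["start_timestamp"]}])
    table = human_presence_table(one, human_events, effort)
    row = table.iloc[0]
    return HumanPresence(
        event_ref=event.get("event_ref", None) if hasattr(event, "get") else None,
        daily_count=int(row["daily_human_detections"]),
        weekly_rate=None if pd.isna(row["weekly_human_rate"]) else float(row["weekly_human_rate"]),
        monthly_rate=None if pd.isna(row["monthly_human_rate"]) else float(row["monthly_human_rate"]),
    )


# --- assembly --------------------------------------------------------------

def assemble_model_table(
    species_events: pd.DataFrame,
    stations: pd.DataFrame,
    human_events: pd.DataFrame,
    effort: pd.DataFrame,
    utc_offset_hours: float,
    per_station_solar: bool = True,
    reference: Optional[SolarContext] = None,
) -> pd.DataFrame:
    """One row per wildlife event: nocturnality response plus raw covariates.

    ``stations`` must carry ``latitude``/``longitude`` (for solar geometry)
    and the per-station covariates ``trail_density``, ``road_density``,
    ``dist_boundary``, ``crown_closure``. Solar noon is taken at each
    station's own coordinates unless ``per_station_solar`` is False, in which
    case ``reference`` is used for every event. Rows with any missing
    covariate (e.g. a zero-effort week) are dropped and counted in the log.
    """
    if species_events.empty:
        species = species_events["species"].iloc[0] if len(species_events) else "<unknown>"
        raise ValueError(f"no events to assemble for species {species!r}")
    species = species_events["species"].iloc[0]

    needed = {"trail_density", "road_density", "dist_boundary", "crown_closure"}
    missing_cols = needed - set(stations.columns)
    if missing_cols:
        raise ValueError(f"station table missing covariate columns: {sorted(missing_cols)}")

    st = stations.set_index("station_id")
    df = species_events.reset_index(drop=True).copy()

    if per_station_solar:
        lat = st.loc[df["station_id"], "latitude"].to_numpy(dtype=float)
        lon = st.loc[df["station_id"], "longitude"].to_numpy(dtype=float)
        noct = np.empty(len(df))
        ts = pd.DatetimeIndex(df["start_timestamp"])
        # group by station to vectorise within each context
        for sid, idx in df.groupby("station_id").indices.items():
            ctx = SolarContext(float(st.at[sid, "latitude"]), float(st.at[sid, "longitude"]), utc_offset_hours)
            noct[idx] = nocturnality(ts[idx], ctx)
        del lat, lon
    else:
        if reference is None:
            raise ValueError("reference SolarContext required when per_station_solar=False")
        noct = nocturnality(pd.DatetimeIndex(df["start_timestamp"]), reference)

    table = pd.DataFrame(
        {
            "species": species,
            "station_id": df["station_id"].to_numpy(),
            "start_timestamp": df["start_timestamp"].to_numpy(),
            "nocturnality": noct,
        }
    )
    human = human_presence_table(df, human_events, effort)
    table = pd.concat([table, human.reset_index(drop=True)], axis=1)
    for col in ("trail_density", "road_density", "dist_boundary", "crown_closure"):
        table[col] = st.loc[df["station_id"], col].to_numpy(dtype=float)
    table["lunar_fraction"] = lunar_fraction(
        pd.DatetimeIndex(df["start_timestamp"]), utc_offset_hours
    )

    before = len(table)
    table = table.dropna(subset=list(PREDICTOR_COLUMNS))
    dropped = before - len(table)
    if dropped:
        logger.warning(
            "%s: dropped %d of %d events with missing covariates (zero-effort periods)",
            species, dropped, before,
        )
    return table.reset_index(drop=True)
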