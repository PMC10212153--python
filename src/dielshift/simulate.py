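"""Synthetic camera-trap study generator.

Emulates the structure the analysis assumes: a grid-less planar landscape
(local equirectangular frame, meters, anchored at a reference
latitude/longitude) holding 58 stations over an ~18-month window, with

* per-station infrastructure geometry (trail and road polylines laid down
  inside each station's 500 m buffer so that recomputing density from the
  geometry reproduces the sampled covariate exactly; a straight east-west
  boundary line at y = 0 so distance-to-boundary equals the station's y),
* camera effort with independent per-day outages,
* diurnally concentrated human traffic whose log-intensity rises with
  standardized trail density,
* wildlife detection events whose nocturnality is a linear function of
  z-scaled covariates plus Gaussian noise, reflected into [0, 12] and
  converted back to a clock timestamp on either side of that date's solar
  noon.

Event dates at one station are drawn without replacement with at least two
calendar days between events, which structurally guarantees the 30-minute
independence gap, so filtering preserves event counts and the drawn
nocturnality values round-trip exactly through the event/astro modules.

Ground truth (coefficients on the standardized scale, residual SD, the
per-station covariates) is returned for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import LineString, mapping

from .astro import SolarContext, lunar_fraction, solar_noon
from .covariates import human_presence_table
from .events import filter_independent_events

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_stations",
    "simulate_effort",
    "simulate_human_activity",
    "simulate_wildlife_detections",
    "simulate_dataset",
    "simulate_regression_dataset",
    "write_dataset",
]

METERS_PER_DEG_LAT = 111_320.0

# Study-scale defaults: six focal species of a representative 58-station
# camera grid, with per-station expected event counts and nocturnality
# intercepts (decimal hours) matching that campaign's per-species event
# totals and mean nocturnalities.
DEFAULT_SPECIES_EVENT_MEANS: Mapping[str, float] = {
    "cougar": 46 / 58,
    "black_bear": 290 / 58,
    "black_tailed_deer": 709 / 58,
    "snowshoe_hare": 248 / 58,
    "coyote": 416 / 58,
    "bobcat": 203 / 58,
}
DEFAULT_SPECIES_INTERCEPTS: Mapping[str, float] = {
    "cougar": 6.47,
    "black_bear": 4.70,
    "black_tailed_deer": 5.74,
    "snowshoe_hare": 9.23,
    "coyote": 7.27,
    "bobcat": 8.11,
}
# Coefficients on the standardized covariate scale (decimal hours per SD),
# magnitudes representative of the effects the analysis is meant to detect.
DEFAULT_BETA: Mapping[str, float] = {
    "weekly_human_rate": 0.35,
    "trail_density": 0.8,
    "road_density": -0.9,
    "dist_boundary": -0.3,
    "lunar_fraction": 0.27,
    "crown_closure": -0.35,
}
DEFAULT_COVARIATE_SPEC: Mapping[str, Mapping[str, float]] = {
    # stratified on/off-feature mixture mirroring the camera deployment
    # design (33/58 stations on trails or roads, the rest off-feature):
    # on-feature densities are gamma with the given mean (m/m^2; one full
    # chord through a 500 m buffer is ~1.27e-3), off-feature densities are
    # uniform on [0, off_max] (a feature clipping the buffer's edge)
    "trail_density": {"on_fraction": 33 / 58, "on_mean": 8.0e-4, "on_shape": 6.0,
                      "off_max": 1.5e-4},
    "road_density": {"on_fraction": 0.33, "on_mean": 6.0e-4, "on_shape": 6.0,
                     "off_max": 1.0e-4},
    # beta distribution for crown closure (temperate-rainforest canopies)
    "crown_closure": {"a": 4.0, "b": 2.0},
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator. Defaults are the study scale:
    58 stations, March 2019 - September 2020, UTC-8 near 49.4N/-122.5E,
    ~4.7 human detections per camera-day with 87.8% inside 09:00-18:00."""

    n_stations: int = 58
    extent_m: float = 20_000.0
    study_start: date = date(2019, 3, 1)
    study_end: date = date(2020, 9, 1)
    utc_offset_hours: float = -8.0
    ref_latitude: float = 49.4
    ref_longitude: float = -122.5
    covariate_spec: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_SPEC))
    human_baseline_per_day: float = 4.7
    # log-linear effect of standardized trail density on human intensity,
    # plus independent lognormal station-to-station heterogeneity
    # (trailhead popularity varies beyond what density explains); together
    # these keep the realized correlation between human detection rates and
    # trail density below the 0.7 collinearity screen, matching the
    # covariate structure the analysis assumes
    human_trail_effect: float = 0.5
    human_station_sd: float = 0.8
    human_diurnal_window: Tuple[float, float] = (9.0, 18.0)
    human_diurnal_fraction: float = 0.878
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercept: float = 6.0
    species_intercepts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_INTERCEPTS))
    sigma: float = 2.5
    events_per_station_mean: float = 34.0
    species_event_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_EVENT_MEANS))
    effort_gap_rate: float = 0.1
    buffer_radius_m: float = 500.0
    min_station_separation_m: float = 1_100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 2:
            raise ValueError("n_stations must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        w0, w1 = self.human_diurnal_window
        if not (0 <= w0 < 24 and 0 <= w1 < 24):
            raise ValueError("human_diurnal_window hours must lie in [0, 24)")
        if not 0 <= self.effort_gap_rate <= 1:
            raise ValueError("effort_gap_rate must be in [0, 1]")
        if not 0 <= self.human_diurnal_fraction <= 1:
            raise ValueError("human_diurnal_fraction must be in [0, 1]")

    @property
    def species(self) -> Sequence[str]:
        return list(self.species_event_means)

    def solar_context(self) -> SolarContext:
        return SolarContext(self.ref_latitude, self.ref_longitude, self.utc_offset_hours)

    def station_context(self, latitude: float, longitude: float) -> SolarContext:
        return SolarContext(latitude, longitude, self.utc_offset_hours)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: per-species standardized coefficients
    (including the intercept), the residual SD, and station covariates."""

    beta_true: Dict[str, Dict[str, float]]
    sigma_true: float
    per_station_covariates: pd.DataFrame
    seed: int
    # one row per generated event: station, species, timestamp and the
    # nocturnality value actually drawn (for round-trip checks)
    per_event: Optional[pd.DataFrame] = None


_STAGE_IDS = {"stations": 1, "effort": 2, "human": 3, "wildlife": 4}


def _stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STAGE_IDS[stage]]))


# --- stations and geometry -------------------------------------------------

def _place_stations(rng: np.random.Generator, n: int, extent: float, sep: float) -> np.ndarray:
    if extent < sep:
        raise ValueError(
            f"extent {extent} m cannot hold {n} stations {sep} m apart")
    pts: list = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > 200_000:
            raise ValueError(
                f"extent {extent} m too small to place {n} stations {sep} m apart")
        cand = rng.uniform(sep / 2, extent - sep / 2, size=2)
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= sep * sep for p in pts):
            pts.append(cand)
    return np.asarray(pts)


def _chords_for_density(rng: np.random.Generator, center: np.ndarray, radius: float,
                        density: float) -> list[LineString]:
    """Straight segments inside the station's disk totalling exactly
    density * pi * r^2 meters."""
    target = density * np.pi * radius * radius
    segments = []
    remaining = target
    while remaining > 1e-9:
        angle = rng.uniform(0, np.pi)
        h = rng.uniform(-0.8 * radius, 0.8 * radius)
        half = np.sqrt(radius * radius - h * h)
        d = np.array([np.cos(angle), np.sin(angle)])
        nvec = np.array([-np.sin(angle), np.cos(angle)])
        base = center + h * nvec
        if 2 * half <= remaining:
            segments.append(LineString([base - half * d, base + half * d]))
            remaining -= 2 * half
        else:
            shift_max = half - remaining / 2
            u = rng.uniform(-shift_max, shift_max) if shift_max > 0 else 0.0
            a = base + (u - remaining / 2) * d
            b = base + (u + remaining / 2) * d
            segments.append(LineString([a, b]))
            remaining = 0.0
    return segments


def simulate_stations(config: SimulationConfig):
    """Sample station locations and lay down infrastructure geometry.

    Returns ``(stations, geoms)``: a station table with planar and geographic
    coordinates plus covariates, and a dict of line layers (``trails``,
    ``roads``, ``boundary``). Station buffers are kept disjoint (minimum
    separation > 2x the buffer radius), and each station's trail/road
    polylines lie inside its own buffer, so densities recomputed from the
    geometry match the sampled covariates exactly.
    """
    rng = _stage_rng(config, "stations")
    xy = _place_stations(rng, config.n_stations, config.extent_m,
                         config.min_station_separation_m)
    n = config.n_stations

    spec = config.covariate_spec

    def _line_density(name):
        pars = spec.get(name, {})
        if "median" in pars:  # lognormal alternative
            if pars["median"] <= 0:
                return np.zeros(n)
            return pars["median"] * np.exp(rng.normal(0.0, pars.get("sigma", 0.0), size=n))
        on_frac = pars.get("on_fraction", 0.0)
        on_mean = pars.get("on_mean", 0.0)
        if on_frac <= 0 or on_mean <= 0:
            return np.zeros(n)
        shape = pars.get("on_shape", 6.0)
        on = rng.random(n) < on_frac
        dens = rng.uniform(0.0, pars.get("off_max", 0.0), size=n)
        dens[on] = rng.gamma(shape, on_mean / shape, size=int(on.sum()))
        return dens

    trail_density = _line_density("trail_density")
    road_density = _line_density("road_density")
    cc = spec.get("crown_closure", {"a": 4.0, "b": 2.0})
    crown = rng.beta(cc["a"], cc["b"], size=n)

    trails, roads = [], []
    for i in range(n):
        trails.extend(_chords_for_density(rng, xy[i], config.buffer_radius_m, trail_density[i]))
        roads.extend(_chords_for_density(rng, xy[i], config.buffer_radius_m, road_density[i]))
    boundary = LineString([(-config.extent_m, 0.0), (2 * config.extent_m, 0.0)])

    lat = config.ref_latitude + xy[:, 1] / METERS_PER_DEG_LAT
    lon = config.ref_longitude + xy[:, 0] / (
        METERS_PER_DEG_LAT * np.cos(np.deg2rad(config.ref_latitude)))
    stations = pd.DataFrame({
        "station_id": [f"CT{i + 1:02d}" for i in range(n)],
        "x": xy[:, 0],
        "y": xy[:, 1],
        "latitude": lat,
        "longitude": lon,
        "trail_density": trail_density,
        "road_density": road_density,
        "dist_boundary": xy[:, 1],
        "crown_closure": crown,
    })
    geoms = {"trails": trails, "roads": roads, "boundary": boundary}
    return stations, geoms


# --- effort ----------------------------------------------------------------

def simulate_effort(config: SimulationConfig, stations: pd.DataFrame) -> pd.DataFrame:
    """Per-station daily activity flags: each camera-day is independently
    inactive with probability ``effort_gap_rate``."""
    rng = _stage_rng(config, "effort")
    days = pd.date_range(config.study_start, config.study_end - timedelta(days=1), freq="D")
    if len(days) == 0:
        raise ValueError("empty study interval")
    frames = []
    for sid in stations["station_id"]:
        active = rng.random(len(days)) >= config.effort_gap_rate
        frames.append(pd.DataFrame({"station_id": sid, "date": days, "active": active}))
    return pd.concat(frames, ignore_index=True)


# --- humans ----------------------------------------------------------------

def _draw_clock_hours(rng, n, window, in_fraction):
    w0, w1 = window
    inside = rng.random(n) < in_fraction
    hours = np.empty(n)
    hours[inside] = rng.uniform(w0, w1, size=inside.sum())
    n_out = (~inside).sum()
    # uniform over the complement of the window on the 24 h circle
    out_len = 24.0 - (w1 - w0)
    u = rng.uniform(0.0, out_len, size=n_out)
    hours[~inside] = np.where(u < w0, u, u + (w1 - w0))
    return hours


def simulate_human_activity(config: SimulationConfig, stations: pd.DataFrame,
                            effort: pd.DataFrame) -> pd.DataFrame:
    """Human detection records: per active camera-day a Poisson count whose
    log-mean is log(baseline) + effect x standardized trail density, with a
    configurable fraction of detection times inside the diurnal window."""
    rng = _stage_rng(config, "human")
    if config.human_baseline_per_day <= 0:
        return pd.DataFrame(columns=["station_id", "species", "timestamp"])
    td = stations["trail_density"].to_numpy(dtype=float)
    sd = td.std(ddof=1)
    z = (td - td.mean()) / sd if sd > 0 else np.zeros_like(td)
    station_effect = rng.normal(0.0, config.human_station_sd, size=len(td))
    lam = np.exp(np.log(config.human_baseline_per_day)
                 + config.human_trail_effect * z + station_effect)
    lam_by_station = dict(zip(stations["station_id"], lam))

    active = effort[effort["active"].astype(bool)]
    counts = rng.poisson(active["station_id"].map(lam_by_station).to_numpy(dtype=float))
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=["station_id", "species", "timestamp"])
    rep_station = np.repeat(active["station_id"].to_numpy(), counts)
    rep_date = np.repeat(active["date"].to_numpy(), counts)
    hours = _draw_clock_hours(rng, total, config.human_diurnal_window,
                              config.human_diurnal_fraction)
    ts = pd.DatetimeIndex(rep_date) + pd.to_timedelta(np.round(hours * 3600.0), unit="s")
    return pd.DataFrame({"station_id": rep_station, "species": "human", "timestamp": ts})


# --- wildlife --------------------------------------------------------------

def _sample_spaced_days(rng: np.random.Generator, day_ordinals: np.ndarray,
                        n: int, min_gap_days: int = 2) -> np.ndarray:
    """Greedy sample of n day ordinals pairwise >= min_gap_days apart."""
    order = rng.permutation(day_ordinals)
    chosen: list = []
    taken: set = set()
    for d in order:
        if len(chosen) == n:
            break
        if all((d + off) not in taken for off in range(-(min_gap_days - 1), min_gap_days)):
            chosen.append(d)
            taken.add(int(d))
    return np.asarray(sorted(chosen))


def _reflect_0_12(values: np.ndarray) -> np.ndarray:
    r = np.mod(values, 24.0)
    return np.where(r > 12.0, 24.0 - r, r)


def simulate_wildlife_detections(config: SimulationConfig, stations: pd.DataFrame,
                                 effort: Optional[pd.DataFrame] = None,
                                 human_records: Optional[pd.DataFrame] = None):
    """Wildlife detection records plus ground truth.

    Per species: station event counts are Poisson with the configured mean;
    event dates are active days >= 2 days apart; nocturnality is
    intercept + beta . z + noise reflected into [0, 12]; the timestamp sits
    that many decimal hours before or after the date's solar noon (fair coin,
    constrained to stay on the same calendar date). Human-presence covariates
    in the linear predictor are the same day/week/month measures the pipeline
    recomputes, built from the 1-minute-filtered human events.
    """
    rng = _stage_rng(config, "wildlife")
    if effort is None:
        effort = simulate_effort(config, stations)
    if human_records is None:
        human_records = simulate_human_activity(config, stations, effort)
    if len(human_records):
        human_events = filter_independent_events(human_records, threshold_minutes=1.0,
                                                 group_keys=("station_id", "species"))
    else:
        human_events = pd.DataFrame(columns=["station_id", "species", "start_timestamp",
                                             "n_records"])

    st = stations.set_index("station_id")
    active = effort[effort["active"].astype(bool)]
    active_days = {sid: pd.DatetimeIndex(grp["date"]).normalize()
                   for sid, grp in active.groupby("station_id")}

    needs_human = any(k in config.beta for k in
                      ("daily_human_detections", "weekly_human_rate", "monthly_human_rate"))

    all_records = []
    beta_true: Dict[str, Dict[str, float]] = {}
    for species, mean_events in config.species_event_means.items():
        rows = []
        for sid in stations["station_id"]:
            days = active_days.get(sid)
            if days is None or len(days) == 0:
                continue
            count = int(rng.poisson(mean_events))
            if count == 0:
                continue
            ordinals = np.array([d.toordinal() for d in days.date])
            chosen = _sample_spaced_days(rng, ordinals, count)
            for ordn in chosen:
                rows.append((sid, date.fromordinal(int(ordn))))
        if not rows:
            continue
        ev = pd.DataFrame(rows, columns=["station_id", "event_date"])
        n_ev = len(ev)

        # covariate matrix in the pipeline's raw units
        cov = pd.DataFrame(index=ev.index)
        for col in ("trail_density", "road_density", "dist_boundary", "crown_closure"):
            cov[col] = st.loc[ev["station_id"], col].to_numpy(dtype=float)
        noon_by_station = {}
        for sid in ev["station_id"].unique():
            ctx = config.station_context(float(st.at[sid, "latitude"]),
                                         float(st.at[sid, "longitude"]))
            dates_s = pd.DatetimeIndex(
                ev.loc[ev["station_id"] == sid, "event_date"].map(pd.Timestamp))
            noon_by_station[sid] = (ctx, dates_s)
        noon_hours = np.empty(n_ev)
        for sid, (ctx, dates_s) in noon_by_station.items():
            idx = ev.index[ev["station_id"] == sid]
            noon_hours[idx] = solar_noon(dates_s, ctx)
        noon_ts = pd.DatetimeIndex(ev["event_date"].map(pd.Timestamp)) + pd.to_timedelta(
            np.round(noon_hours * 3600.0), unit="s")
        cov["lunar_fraction"] = lunar_fraction(noon_ts, config.utc_offset_hours)
        if needs_human:
            hp = human_presence_table(
                pd.DataFrame({"station_id": ev["station_id"], "start_timestamp": noon_ts}),
                human_events, effort)
            for col in hp.columns:
                cov[col] = hp[col].to_numpy()

        # linear predictor on the standardized scale
        intercept = config.species_intercepts.get(species, config.intercept)
        eta = np.full(n_ev, intercept, dtype=float)
        used = {"intercept": intercept}
        for name, coef in config.beta.items():
            if coef == 0.0 or name not in cov.columns:
                if name in cov.columns:
                    used[name] = 0.0
                continue
            x = cov[name].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd > 0:
                eta += coef * (x - x.mean()) / sd
                used[name] = coef
            else:
                used[name] = 0.0
        noct = _reflect_0_12(eta + rng.normal(0.0, config.sigma, size=n_ev))

        side = np.where(rng.random(n_ev) < 0.5, -1.0, 1.0)
        clock = noon_hours + side * noct
        flip = (clock < 0.0) | (clock >= 24.0)
        clock = np.where(flip, noon_hours - side * noct, clock)
        ts = pd.DatetimeIndex(ev["event_date"].map(pd.Timestamp)) + pd.to_timedelta(
            np.round(clock * 3600.0), unit="s")
        all_records.append(pd.DataFrame({
            "station_id": ev["station_id"].to_numpy(),
            "species": species,
            "timestamp": ts,
            "nocturnality_drawn": noct,
        }))
        beta_true[species] = used

    records = (pd.concat(all_records, ignore_index=True) if all_records
               else pd.DataFrame(columns=["station_id", "species", "timestamp",
                                          "nocturnality_drawn"]))
    records = records.sort_values(["station_id", "species", "timestamp"]).reset_index(drop=True)
    truth = SyntheticTruth(beta_true=beta_true, sigma_true=config.sigma,
                           per_station_covariates=stations.copy(), seed=config.seed,
                           per_event=records.rename(
                               columns={"nocturnality_drawn": "nocturnality"}).copy())
    records = records.drop(columns="nocturnality_drawn")
    return records, truth


def simulate_dataset(config: SimulationConfig):
    """Full study bundle: stations+geometry, effort, human records, wildlife
    records, truth. Deterministic under a fixed config (seed included)."""
    stations, geoms = simulate_stations(config)
    effort = simulate_effort(config, stations)
    humans = simulate_human_activity(config, stations, effort)
    wildlife, truth = simulate_wildlife_detections(config, stations, effort, humans)
    detections = pd.concat([humans, wildlife], ignore_index=True)
    detections = detections.sort_values(["station_id", "species", "timestamp"]).reset_index(
        drop=True)
    return {
        "stations": stations,
        "geoms": geoms,
        "effort": effort,
        "detections": detections,
        "truth": truth,
        "config": config,
    }


def simulate_regression_dataset(n: int, beta: Sequence[float], sigma: float,
                                seed: Optional[int] = None,
                                names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Plain linear-Gaussian testbed: z-scaled iid normal predictors and
    response intercept-less ``beta[0] + X @ beta[1:] + N(0, sigma)``, no
    reflection. Used for CI-calibration checks of the fitted model under its
    own assumptions."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p = len(beta) - 1
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    y = beta[0] + X @ beta[1:] + rng.normal(0.0, sigma, size=n)
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    out = pd.DataFrame(X, columns=list(names))
    out.insert(0, "nocturnality", y)
    return out


# --- file output -----------------------------------------------------------

def _offset_str(hours: float) -> str:
    sign = "+" if hours >= 0 else "-"
    h = int(abs(hours))
    m = int(round((abs(hours) - h) * 60))
    return f"{sign}{h:02d}:{m:02d}"


def write_dataset(out_dir, bundle) -> None:
    """Write a simulated bundle as plain-text files: detections.csv,
    effort.csv, stations.csv, GeoJSON line layers, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config: SimulationConfig = bundle["config"]
    off = _offset_str(config.utc_offset_hours)

    det = bundle["detections"].copy()
    det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S") + off
    det.to_csv(out / "detections.csv", index=False)

    eff = bundle["effort"].copy()
    eff["date"] = pd.DatetimeIndex(eff["date"]).strftime("%Y-%m-%d")
    eff.to_csv(out / "effort.csv", index=False)

    bundle["stations"].to_csv(out / "stations.csv", index=False)

    geoms = bundle["geoms"]
    for name in ("trails", "roads", "boundary"):
        layer = geoms[name]
        feats = layer if isinstance(layer, (list, tuple)) else [layer]
        fc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {}, "geometry": mapping(g)}
                for g in feats
            ],
        }
        (out / f"{name}.geojson").write_text(json.dumps(fc))

    truth: SyntheticTruth = bundle["truth"]
    payload = {
        "beta_true": truth.beta_true,
        "sigma_true": truth.sigma_true,
        "seed": truth.seed,
        "utc_offset_hours": config.utc_offset_hours,
        "per_station_covariates": truth.per_station_covariates.to_dict(orient="list"),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
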