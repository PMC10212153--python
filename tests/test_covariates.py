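"""Geometric and human-presence covariates against analytic and brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from dielshift import (
    assemble_model_table,
    distance_to_boundary,
    human_presence_for_event,
    human_presence_table,
    line_density_in_buffer,
)

R = 500.0


# --- line density ----------------------------------------------------------

def test_empty_geometry_gives_zero_density():
    assert line_density_in_buffer([], (0.0, 0.0), R) == 0.0
    assert line_density_in_buffer(LineString(), (0.0, 0.0), R) == 0.0


def test_full_chord_through_center():
    # chord through the station spanning the disk: length 2r, density 2/(pi r)
    line = LineString([(-10 * R, 0.0), (10 * R, 0.0)])
    dens = line_density_in_buffer([line], (0.0, 0.0), R)
    assert dens == pytest.approx(2.0 / (np.pi * R), rel=1e-12)
    assert dens == pytest.approx(1.2732e-3, rel=1e-4)


def test_segment_fully_inside_counts_whole_length():
    line = LineString([(-100.0, 50.0), (200.0, 50.0)])
    dens = line_density_in_buffer([line], (0.0, 0.0), R)
    assert dens == pytest.approx(300.0 / (np.pi * R * R), rel=1e-12)


def test_segment_outside_counts_nothing():
    line = LineString([(2 * R, -R), (2 * R, R)])
    assert line_density_in_buffer([line], (0.0, 0.0), R) == 0.0


def test_doubling_lines_doubles_density():
    rng = np.random.default_rng(1)
    lines = [LineString(rng.uniform(-2 * R, 2 * R, size=(2, 2))) for _ in range(20)]
    d1 = line_density_in_buffer(lines, (0.0, 0.0), R)
    d2 = line_density_in_buffer(lines + lines, (0.0, 0.0), R)
    assert d2 == pytest.approx(2 * d1, rel=1e-12)


def _dense_sampling_density(lines, center, radius, step=0.05):
    """Monte-Carlo-style oracle: walk each segment in tiny steps and count
    the length of the pieces whose midpoints fall inside the disk."""
    cx, cy = center
    total = 0.0
    for line in lines:
        coords = np.asarray(line.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            length = float(np.hypot(*(b - a)))
            if length == 0:
                continue
            n = max(2, int(length / step))
            t = (np.arange(n) + 0.5) / n
            mid = a + t[:, None] * (b - a)
            inside = (mid[:, 0] - cx) ** 2 + (mid[:, 1] - cy) ** 2 <= radius**2
            total += inside.mean() * length
    return total / (np.pi * radius * radius)


def test_density_matches_dense_sampling_oracle():
    rng = np.random.default_rng(8)
    for _ in range(5):
        lines = [LineString(rng.uniform(-1.5 * R, 1.5 * R, size=(2, 2)))
                 for _ in range(12)]
        exact = line_density_in_buffer(lines, (0.0, 0.0), R)
        approx = _dense_sampling_density(lines, (0.0, 0.0), R)
        assert exact == pytest.approx(approx, rel=5e-3)


# --- distance to boundary --------------------------------------------------

def test_distance_on_and_above_boundary():
    boundary = LineString([(-1000.0, 0.0), (1000.0, 0.0)])
    assert distance_to_boundary((0.0, 0.0), boundary) == 0.0
    assert distance_to_boundary((0.0, 250.0), boundary) == pytest.approx(250.0)


def test_distance_matches_brute_force_oracle():
    rng = np.random.default_rng(5)

    def point_segment_distance(p, a, b):
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        return float(np.hypot(*(p - (a + t * ab))))

    for _ in range(30):
        segs = rng.uniform(-1000, 1000, size=(4, 2, 2))
        boundary = [LineString(s) for s in segs]
        p = rng.uniform(-1000, 1000, size=2)
        oracle = min(point_segment_distance(p, s[0], s[1]) for s in segs)
        assert distance_to_boundary(tuple(p), boundary) == pytest.approx(oracle, abs=1e-9)


def test_empty_boundary_is_configuration_error():
    with pytest.raises(ValueError, match="empty"):
        distance_to_boundary((0.0, 0.0), LineString())


# --- human presence --------------------------------------------------------

def _effort(station, dates, active=True):
    return pd.DataFrame({"station_id": station, "date": pd.to_datetime(dates),
                         "active": active})


def _human_events(station, times):
    return pd.DataFrame({"station_id": station, "species": "human",
                         "start_timestamp": pd.to_datetime(times), "n_records": 1})


def test_weekly_rate_seven_events_seven_days():
    # ISO week 2019-W23: Mon 2019-06-03 .. Sun 2019-06-09
    days = pd.date_range("2019-06-03", "2019-06-09")
    humans = _human_events("CT01", [d + pd.Timedelta(hours=12) for d in days])
    effort = _effort("CT01", days)
    event = {"station_id": "CT01", "start_timestamp": pd.Timestamp("2019-06-05 08:00")}
    hp = human_presence_for_event(event, humans, effort)
    assert hp.weekly_rate == pytest.approx(1.0)
    assert hp.daily_count == 1


def test_monthly_rate_three_events_ten_active_days():
    active_days = pd.date_range("2019-06-01", "2019-06-10")
    inactive = pd.date_range("2019-06-11", "2019-06-30")
    effort = pd.concat([_effort("CT01", active_days, True),
                        _effort("CT01", inactive, False)])
    humans = _human_events("CT01", ["2019-06-02 10:00", "2019-06-04 11:00",
                                    "2019-06-08 15:00"])
    event = {"station_id": "CT01", "start_timestamp": pd.Timestamp("2019-06-05 03:00")}
    hp = human_presence_for_event(event, humans, effort)
    assert hp.monthly_rate == pytest.approx(3 / 10)


def test_zero_effort_week_gives_missing_rate():
    # camera entirely off during the event's ISO week
    effort = pd.concat([
        _effort("CT01", pd.date_range("2019-06-03", "2019-06-09"), False),
        _effort("CT01", pd.date_range("2019-06-10", "2019-06-16"), True),
    ])
    event = {"station_id": "CT01", "start_timestamp": pd.Timestamp("2019-06-05 03:00")}
    hp = human_presence_for_event(event, _human_events("CT01", []), effort)
    assert hp.weekly_rate is None
    assert hp.monthly_rate is not None  # month has active days


def test_station_missing_from_effort_is_error():
    effort = _effort("CT01", pd.date_range("2019-06-03", "2019-06-09"))
    events = pd.DataFrame({"station_id": ["CT99"],
                           "start_timestamp": [pd.Timestamp("2019-06-05")]})
    with pytest.raises(ValueError, match="CT99"):
        human_presence_table(events, _human_events("CT01", []), effort)


def test_rates_invariant_to_event_order():
    days = pd.date_range("2019-06-03", "2019-06-16")
    effort = _effort("CT01", days)
    times = ["2019-06-04 09:00", "2019-06-03 10:00", "2019-06-08 17:00"]
    ev = pd.DataFrame({"station_id": "CT01",
                       "start_timestamp": pd.to_datetime(["2019-06-05 12:00"])})
    a = human_presence_table(ev, _human_events("CT01", times), effort)
    b = human_presence_table(ev, _human_events("CT01", times[::-1]), effort)
    pd.testing.assert_frame_equal(a, b)


# --- assembly --------------------------------------------------------------

def _toy_setup():
    stations = pd.DataFrame({
        "station_id": ["CT01", "CT02"],
        "x": [0.0, 1000.0], "y": [100.0, 200.0],
        "latitude": [49.4, 49.41], "longitude": [-122.5, -122.49],
        "trail_density": [1e-4, 3e-4], "road_density": [0.0, 1e-4],
        "dist_boundary": [100.0, 200.0], "crown_closure": [0.6, 0.8],
    })
    effort = pd.concat([
        _effort("CT01", pd.date_range("2019-06-01", "2019-06-30")),
        _effort("CT02", pd.date_range("2019-06-01", "2019-06-30")),
    ])
    humans = _human_events("CT01", ["2019-06-05 10:00", "2019-06-06 11:00"])
    return stations, effort, humans


def test_assemble_shapes_and_columns():
    stations, effort, humans = _toy_setup()
    events = pd.DataFrame({
        "station_id": ["CT01", "CT01", "CT02", "CT02", "CT02"],
        "species": "coyote",
        "start_timestamp": pd.to_datetime([
            "2019-06-05 04:00", "2019-06-10 23:00", "2019-06-07 12:30",
            "2019-06-15 02:00", "2019-06-20 19:00"]),
    })
    table = assemble_model_table(events, stations, humans, effort, -8.0)
    assert len(table) == 5
    expected = {"daily_human_detections", "weekly_human_rate", "monthly_human_rate",
                "trail_density", "road_density", "dist_boundary", "lunar_fraction",
                "crown_closure"}
    assert expected <= set(table.columns)
    assert table["nocturnality"].between(0, 12).all()
    assert table["lunar_fraction"].between(0, 1).all()


def test_assemble_drops_zero_effort_rows():
    stations, effort, humans = _toy_setup()
    # CT01 off the whole week of 2019-06-17
    off = (effort["station_id"] == "CT01") & effort["date"].between(
        "2019-06-17", "2019-06-23")
    effort.loc[off, "active"] = False
    events = pd.DataFrame({
        "station_id": ["CT01"] * 4 + ["CT01"],
        "species": "coyote",
        "start_timestamp": pd.to_datetime([
            "2019-06-05 04:00", "2019-06-10 23:00", "2019-06-12 12:30",
            "2019-06-25 02:00", "2019-06-18 19:00"]),  # last one in dead week
    })
    table = assemble_model_table(events, stations, humans, effort, -8.0)
    assert len(table) == 4


def test_assemble_missing_station_column_is_error():
    stations, effort, humans = _toy_setup()
    events = pd.DataFrame({"station_id": ["CT01"], "species": "coyote",
                           "start_timestamp": [pd.Timestamp("2019-06-05 04:00")]})
    with pytest.raises(ValueError, match="crown_closure"):
        assemble_model_table(events, stations.drop(columns="crown_closure"),
                             humans, effort, -8.0)


def test_assemble_empty_events_is_error():
    stations, effort, humans = _toy_setup()
    empty = pd.DataFrame(columns=["station_id", "species", "start_timestamp"])
    with pytest.raises(ValueError, match="no events"):
        assemble_model_table(empty, stations, humans, effort, -8.0)
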