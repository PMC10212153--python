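"""Readers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import shape

from .events import read_detections

__all__ = ["read_detections", "read_effort", "read_stations", "read_lines", "read_truth"]


def read_effort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str})
    df["date"] = pd.to_datetime(df["date"])
    df["active"] = df["active"].astype(bool)
    return df


def read_stations(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"station_id": str})


def read_lines(path):
    """Read a GeoJSON FeatureCollection of LineString/MultiLineString."""
    fc = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in fc.get("features", [])]


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
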