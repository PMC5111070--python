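"""Tabular and vector I/O: presence-record CSVs, capture CSVs, GeoJSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

RECORD_COLUMNS = ["x_km", "y_km", "date", "source"]
TRAP_COLUMNS = ["trap_id", "x_km", "y_km"]
DETECTION_COLUMNS = ["individual_id", "sex", "age", "trap_id", "occasion"]


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    records.to_csv(path, index=False, columns=cols)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"x_km", "y_km"} - set(df.columns)
    if missing:
        raise ValueError(f"records file {path} missing columns {sorted(missing)}")
    return df


def write_traps(traps: pd.DataFrame, path: str | Path) -> None:
    traps.to_csv(path, index=False, columns=TRAP_COLUMNS)


def read_traps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"traps file {path} missing columns {sorted(missing)}")
    return df


def write_detections(detections: pd.DataFrame, path: str | Path) -> None:
    detections.to_csv(path, index=False, columns=DETECTION_COLUMNS)


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections file {path} missing columns {sorted(missing)}")
    return df


def geometries_to_geojson(
    geoms: Iterable[BaseGeometry],
    properties: Iterable[dict] | None = None,
    path: str | Path | None = None,
) -> dict:
    """Build (and optionally write) a GeoJSON FeatureCollection."""
    geoms = list(geoms)
    props = list(properties) if properties is not None else [{} for _ in geoms]
    if len(props) != len(geoms):
        raise ValueError("properties length must match geometries")
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geoms, props)
        ],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh, indent=1, sort_keys=True)
    return fc


def geojson_to_geometries(src: str | Path | dict) -> tuple[list[BaseGeometry], list[dict]]:
    """Read a FeatureCollection; returns (geometries, properties)."""
    if isinstance(src, (str, Path)):
        with open(src) as fh:
            src = json.load(fh)
    feats = src.get("features", [])
    geoms = [shape(f["geometry"]) for f in feats]
    props = [f.get("properties") or {} for f in feats]
    return geoms, props
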