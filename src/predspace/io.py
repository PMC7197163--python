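"""Plain-text I/O: fix CSVs, GeoJSON vector layers, truth records.

Fix CSV schema: animal_id, species, sex, timestamp (ISO-8601), x, y,
elevation — one row per fix, projected metres. GeoJSON geometry is handled
through shapely's mapping/shape round trip (coordinates stay in the planar
metric frame; no CRS object is written beyond a note property).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .screening import Track

__all__ = [
    "read_fixes_csv",
    "write_fixes_csv",
    "read_geojson",
    "write_geojson",
]

FIX_COLUMNS = ["animal_id", "species", "sex", "timestamp", "x", "y",
               "elevation"]


def write_fixes_csv(tracks: list[Track], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        df = tr.fixes.copy()
        df["animal_id"] = tr.animal_id
        df["species"] = tr.species
        df["sex"] = tr.sex
        frames.append(df[FIX_COLUMNS + (["status"] if "status" in df else [])])
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


def read_fixes_csv(path: str | Path,
                   fix_intervals: dict[str, float] | None = None
                   ) -> list[Track]:
    """One Track per animal_id; species/sex taken from the first row."""
    df = pd.read_csv(path)
    missing = set(FIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fix CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    tracks = []
    for animal, sub in df.groupby("animal_id", sort=True):
        species = str(sub["species"].iloc[0])
        interval = (fix_intervals or {}).get(species)
        tracks.append(
            Track(
                animal_id=str(animal),
                species=species,
                sex=str(sub["sex"].iloc[0]),
                fixes=sub.drop(columns=["species", "sex"]).reset_index(
                    drop=True),
                fix_interval_h=interval,
            )
        )
    return tracks


def write_geojson(geoms, path: str | Path, properties=None) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    if not isinstance(geoms, (list, tuple)):
        geoms = [geoms]
    properties = properties or [{} for _ in geoms]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path: str | Path):
    """Read a GeoJSON file into (geometries, properties) lists."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        feats = obj["features"]
    elif obj.get("type") == "Feature":
        feats = [obj]
    else:  # bare geometry
        return [shape(obj)], [{}]
    geoms = [shape(f["geometry"]) for f in feats]
    props = [f.get("properties") or {} for f in feats]
    return geoms, props
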