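"""Readers and writers for the package's on-disk formats.

Buoy and VMS position streams travel as plain CSV with ISO-8601 timestamps;
the synthetic world (ports, coastline, fishing-ground cells) as GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import World


def write_positions_csv(df: pd.DataFrame, path) -> None:
    """Write a buoy position stream (id, vessel_id, timestamp, lat, lon, sst, ...)."""
    out = df.rename(columns={"buoy_id": "id", "time": "timestamp"})
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")


def read_positions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={"id": "buoy_id", "timestamp": "time"})
    df["time"] = pd.to_datetime(df["time"], format="ISO8601").dt.tz_localize(None)
    return df


def write_vms_csv(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"vessel_id": "id", "time": "timestamp"})
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")


def read_vms_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={"id": "vessel_id", "timestamp": "time"})
    df["time"] = pd.to_datetime(df["time"], format="ISO8601").dt.tz_localize(None)
    return df


def world_to_geojson(world: World) -> dict:
    """Ports as Point features, coastline as a LineString, cells as Polygons."""
    features = []
    for name, lat, lon in world.ports:
        features.append(
            {
                "type": "Feature",
                "properties": {"kind": "port", "name": name},
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
            }
        )
    features.append(
        {
            "type": "Feature",
            "properties": {"kind": "coastline"},
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(lon), float(lat)] for lat, lon in world.coastline],
            },
        }
    )
    for ilat, ilon in sorted(world.ground_cells):
        ring = [
            [ilon, ilat], [ilon + 1, ilat], [ilon + 1, ilat + 1], [ilon, ilat + 1], [ilon, ilat]
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"kind": "ground_cell", "lat": ilat, "lon": ilon},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    lat0, lat1, lon0, lon1 = world.bbox
    return {
        "type": "FeatureCollection",
        "bbox": [lon0, lat0, lon1, lat1],
        "features": features,
    }


def write_world_geojson(world: World, path) -> None:
    Path(path).write_text(json.dumps(world_to_geojson(world)))


def read_world_geojson(path) -> World:
    data = json.loads(Path(path).read_text())
    ports, coast, cells = [], None, set()
    for f in data["features"]:
        kind = f["properties"]["kind"]
        if kind == "port":
            lon, lat = f["geometry"]["coordinates"]
            ports.append((f["properties"]["name"], lat, lon))
        elif kind == "coastline":
            coast = np.array([[lat, lon] for lon, lat in f["geometry"]["coordinates"]])
        elif kind == "ground_cell":
            cells.add((f["properties"]["lat"], f["properties"]["lon"]))
    lon0, lat0, lon1, lat1 = data["bbox"]
    return World(ports=ports, coastline=coast, ground_cells=cells,
                 bbox=(lat0, lat1, lon0, lon1))
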