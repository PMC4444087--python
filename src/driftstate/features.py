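"""Per-position predictor variables for buoy state classification.

For three consecutive fixes t-1, t, t+1 of a cleaned track, each position
gets: the time intervals after, before and spanning it (s); speed to the next
fix and from the previous fix (m/s); acceleration 2*(speed - speed_before) /
dt_after (m/s^2; the factor 2 is kept as printed in the source formula — it
rescales a monotone transform and classifiers are invariant to it); heading
change; minimum great-circle distance to a port (km); and the water
temperature, its previous value, its change and its change per second.

Heading change defaults to the *literal* difference of absolute bearings
|heading|_{t,t+1} - |heading|_{t-1,t} with bearings in (-180, 180]; the
conventional smallest-signed-turn definition is available via
``heading_mode="turn"``. Track-boundary positions copy the available one-sided
values into the missing side so every position can be classified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geo import haversine_km, initial_bearing

FEATURE_COLUMNS = [
    "dt_after",
    "dt_before",
    "dt_span",
    "speed",
    "speed_before",
    "accel",
    "heading_change",
    "port_dist",
    "sst",
    "sst_before",
    "sst_change",
    "sst_rate",
]


class FeatureError(ValueError):
    pass


def _wrap180(x: np.ndarray) -> np.ndarray:
    return (x + 180.0) % 360.0 - 180.0


def compute_features(
    track: pd.DataFrame,
    ports: np.ndarray,
    heading_mode: str = "literal",
    heading_unit: str = "deg",
) -> pd.DataFrame:
    """Feature table for one buoy track (sorted, one fix per hour, n >= 3)."""
    if heading_mode not in ("literal", "turn"):
        raise ValueError("heading_mode must be 'literal' or 'turn'")
    if heading_unit not in ("deg", "rad"):
        raise ValueError("heading_unit must be 'deg' or 'rad'")
    n = len(track)
    if n < 3:
        raise FeatureError("need at least 3 positions to form t-1, t, t+1")
    t = track["time"].to_numpy()
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)

    dt_step = (t[1:] - t[:-1]) / np.timedelta64(1, "s")  # n-1 gaps
    if np.any(dt_step <= 0):
        raise FeatureError("track times must be strictly increasing")
    dist_m = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) * 1000.0
    v_step = dist_m / dt_step
    brg_step = initial_bearing(lat[:-1], lon[:-1], lat[1:], lon[1:])
    # coincident fixes: bearing undefined; carry the previous leg's bearing
    # (no turn) so heading_change stays defined
    brg_step = pd.Series(brg_step).ffill().bfill().fillna(0.0).to_numpy()

    dt_after = np.r_[dt_step, dt_step[-1]]
    dt_before = np.r_[dt_step[0], dt_step]
    speed = np.r_[v_step, v_step[-1]]
    speed_before = np.r_[v_step[0], v_step]
    h_after = np.r_[brg_step, brg_step[-1]]
    h_before = np.r_[brg_step[0], brg_step]

    if heading_mode == "literal":
        heading_change = np.abs(h_after) - np.abs(h_before)
    else:
        heading_change = _wrap180(h_after - h_before)
    if heading_unit == "rad":
        heading_change = np.radians(heading_change)

    ports = np.asarray(ports, dtype=float)
    port_dist = haversine_km(
        lat[:, None], lon[:, None], ports[None, :, 0], ports[None, :, 1]
    ).min(axis=1)

    sst = track["sst"].to_numpy(dtype=float) if "sst" in track else np.full(n, np.nan)
    sst_before = np.r_[sst[0], sst[:-1]]
    sst_change = sst - sst_before
    sst_rate = sst_change / dt_before

    out = pd.DataFrame(
        {
            "dt_after": dt_after,
            "dt_before": dt_before,
            "dt_span": dt_after + dt_before,
            "speed": speed,
            "speed_before": speed_before,
            "accel": 2.0 * (speed - speed_before) / dt_after,
            "heading_change": heading_change,
            "port_dist": port_dist,
            "sst": sst,
            "sst_before": sst_before,
            "sst_change": sst_change,
            "sst_rate": sst_rate,
        },
        index=track.index,
    )
    return out


def compute_track_features(
    positions: pd.DataFrame,
    ports: np.ndarray,
    heading_mode: str = "literal",
    heading_unit: str = "deg",
) -> pd.DataFrame:
    """Features for every track in a multi-buoy position table.

    Tracks with fewer than 3 positions are skipped. Returns the input columns
    joined with the feature columns, ordered by (buoy_id, time).
    """
    frames = []
    for _, g in positions.sort_values(["buoy_id", "time"], kind="stable").groupby(
        "buoy_id", sort=False
    ):
        if len(g) < 3:
            continue
        g = g.reset_index(drop=True)
        frames.append(pd.concat([g, compute_features(g, ports, heading_mode, heading_unit)], axis=1))
    if not frames:
        raise FeatureError("no track has 3 or more positions")
    return pd.concat(frames, ignore_index=True)
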