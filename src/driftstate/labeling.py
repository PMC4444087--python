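"""Rule-based construction of the learning dataset from VMS overlap.

The true state of a buoy position is established by superimposing the buoy
track on the tracks of nearby fishing vessels: while a buoy rides a vessel its
fixes coincide with the vessel's VMS positions, so small interpolated
buoy-vessel separations indicate "on board" (B). The field practice of doing
this visually is codified as deterministic rules:

(i)   positions closer than ``port_radius`` to a port are B;
(ii)  positions whose interpolated separation from some candidate vessel is
      below ``d_match`` are B, the rest S;
(iii) maximal runs with no VMS support (no vessel fix within ``d_match`` /
      ``t_match``) whose speeds are consistently above ``v_exclude`` — a buoy
      likely carried by a vessel we have no VMS for — are left UNASSIGNED and
      excluded from training;
(iv)  at each B-to-S transition, if speed rises from t to t+1 the boundary is
      shifted so that the slow fix stays B (the deployment tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_km

STATE_UNASSIGNED = "U"


@dataclass
class MatchConfig:
    d_match: float = 5.0        # km
    t_match: float = 24.0       # hours
    port_radius: float = 5.0    # km
    v_exclude: float = 1.5      # m/s
    consistency: float = 0.9    # fraction of run speeds above v_exclude

    def __post_init__(self) -> None:
        if min(self.d_match, self.t_match, self.port_radius, self.v_exclude) <= 0:
            raise ValueError("match thresholds must be strictly positive")


def interpolate_vms(vessel_track: pd.DataFrame, query_times) -> pd.DataFrame:
    """Linear lat/lon interpolation of a VMS track at arbitrary times.

    Times outside the track span get NaN coordinates.
    """
    if len(vessel_track) == 0:
        raise ValueError("empty vessel track")
    vt = vessel_track.sort_values("time", kind="stable")
    ts = vt["time"].to_numpy().astype("datetime64[s]").astype(float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("vessel times must be strictly increasing")
    q = pd.DatetimeIndex(query_times).to_numpy().astype("datetime64[s]").astype(float)
    lat = np.interp(q, ts, vt["lat"].to_numpy(dtype=float))
    lon = np.interp(q, ts, vt["lon"].to_numpy(dtype=float))
    outside = (q < ts[0]) | (q > ts[-1])
    lat[outside] = np.nan
    lon[outside] = np.nan
    return pd.DataFrame({"time": pd.DatetimeIndex(query_times), "lat": lat, "lon": lon})


def _has_support(buoy_track: pd.DataFrame, vms: pd.DataFrame, cfg: MatchConfig) -> np.ndarray:
    """Per buoy position: does some raw VMS fix sit within d_match and t_match."""
    bt = buoy_track["time"].to_numpy().astype("datetime64[s]").astype(float)
    vt = vms["time"].to_numpy().astype("datetime64[s]").astype(float)
    order = np.argsort(vt, kind="stable")
    vt, vlat, vlon = vt[order], vms["lat"].to_numpy()[order], vms["lon"].to_numpy()[order]
    out = np.zeros(len(bt), dtype=bool)
    tol = cfg.t_match * 3600.0
    lo = np.searchsorted(vt, bt - tol, side="right")
    hi = np.searchsorted(vt, bt + tol, side="left")
    blat = buoy_track["lat"].to_numpy(dtype=float)
    blon = buoy_track["lon"].to_numpy(dtype=float)
    for i in range(len(bt)):
        if lo[i] >= hi[i]:
            continue
        d = haversine_km(blat[i], blon[i], vlat[lo[i]:hi[i]], vlon[lo[i]:hi[i]])
        out[i] = bool((d < cfg.d_match).any())
    return out


def select_candidate_vessels(
    buoy_track: pd.DataFrame, vms_tracks: dict[str, pd.DataFrame], cfg: MatchConfig
) -> list[str]:
    """Vessels with at least one fix close in space and time to the buoy."""
    return [
        vid for vid, vms in vms_tracks.items() if _has_support(buoy_track, vms, cfg).any()
    ]


def assign_states(
    buoy_track: pd.DataFrame,
    vms_tracks: dict[str, pd.DataFrame],
    ports: np.ndarray,
    cfg: MatchConfig | None = None,
) -> pd.DataFrame:
    """Label one buoy track with S / B / U states and the rule that fired.

    ``buoy_track`` must carry a ``speed`` column (m/s) for the exclusion rule
    and the tie-break. Returns the track with ``state`` and ``source`` columns.
    """
    cfg = cfg or MatchConfig()
    df = buoy_track.sort_values("time", kind="stable").reset_index(drop=True)
    n = len(df)
    ports = np.asarray(ports, dtype=float)
    port_d = haversine_km(
        df["lat"].to_numpy()[:, None], df["lon"].to_numpy()[:, None],
        ports[None, :, 0], ports[None, :, 1],
    ).min(axis=1)

    candidates = select_candidate_vessels(df, vms_tracks, cfg)
    matched = np.zeros(n, dtype=bool)
    supported = np.zeros(n, dtype=bool)
    for vid in candidates:
        vms = vms_tracks[vid]
        interp = interpolate_vms(vms, df["time"])
        sep = haversine_km(df["lat"], df["lon"], interp["lat"], interp["lon"])
        matched |= np.nan_to_num(sep, nan=np.inf) < cfg.d_match
        supported |= _has_support(df, vms, cfg)

    state = np.where(port_d < cfg.port_radius, "B", np.where(matched, "B", "S")).astype(object)
    source = np.where(port_d < cfg.port_radius, "port-rule", "vms-overlap").astype(object)

    # rule (iii): unsupported runs with consistently high speeds
    speed = df["speed"].to_numpy(dtype=float) if "speed" in df else np.full(n, np.nan)
    unsupported = ~supported & (port_d >= cfg.port_radius)
    i = 0
    while i < n:
        if not unsupported[i]:
            i += 1
            continue
        j = i
        while j < n and unsupported[j]:
            j += 1
        run_speed = speed[i:j]
        finite = run_speed[np.isfinite(run_speed)]
        if finite.size and (finite > cfg.v_exclude).mean() >= cfg.consistency:
            state[i:j] = STATE_UNASSIGNED
            source[i:j] = "speed-exclusion"
        i = j

    # rule (iv): deployment tie-break at B->S transitions
    for k in range(n - 1):
        if state[k] == "B" and state[k + 1] == "S" and source[k] != "port-rule":
            if np.isfinite(speed[k]) and np.isfinite(speed[k + 1]) and speed[k] < speed[k + 1]:
                state[k] = "S"
                source[k] = "tie-break"

    out = df.copy()
    out["state"] = state
    out["source"] = source
    return out


def build_learning_set(
    features: pd.DataFrame,
    vms: pd.DataFrame,
    ports: np.ndarray,
    cfg: MatchConfig | None = None,
) -> pd.DataFrame:
    """Label every track in a feature table; drop UNASSIGNED rows.

    ``features`` holds cleaned positions + feature columns for many buoys;
    ``vms`` the stacked vessel streams (vessel_id, time, lat, lon).
    """
    vms_tracks = {vid: g for vid, g in vms.groupby("vessel_id", sort=False)}
    frames = []
    for _, g in features.groupby("buoy_id", sort=False):
        frames.append(assign_states(g, vms_tracks, ports, cfg))
    out = pd.concat(frames, ignore_index=True)
    return out.loc[out["state"] != STATE_UNASSIGNED].reset_index(drop=True)
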