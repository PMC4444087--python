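"""Ecological outputs derived from classified buoy tracks.

From a track labelled S/B per position: maximal at-sea runs become drift
trajectories (duration, piecewise great-circle distance, end event); S->B
transition points are candidate fishing-set positions; point sets are
gridded on 1-degree cells and optionally smoothed with a 2-D product
Gaussian kernel (rule-of-thumb bandwidths); repeated identical raw fixes far
from ports and close to the coastline are beaching events; and drift time
spent outside historical fishing-ground cells quantifies "ineffective"
effort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo import distance_to_polyline_km, haversine_km


@dataclass
class BeachingConfig:
    min_repeats: int = 3
    port_exclusion_km: float = 10.0
    coast_max_km: float = 5.0
    position_tolerance_deg: float = 0.0  # exact coordinate equality by default

    def __post_init__(self) -> None:
        if self.min_repeats < 3:
            raise ValueError("min_repeats must be >= 3 (2 repeats are a known GPS artifact)")
        if min(self.port_exclusion_km, self.coast_max_km) <= 0:
            raise ValueError("distances must be positive")


def extract_sea_trajectories(classified: pd.DataFrame, state_col: str = "state") -> pd.DataFrame:
    """One row per maximal at-sea run of each buoy.

    Columns: buoy_id, start/end time and position, n_positions, duration_days,
    distance_km (piecewise great-circle), end_event (retrieval if the run is
    followed by an on-board fix, else track_end).
    """
    df = classified.sort_values(["buoy_id", "time"], kind="stable").reset_index(drop=True)
    rows = []
    for bid, g in df.groupby("buoy_id", sort=False):
        s = g[state_col].to_numpy()
        lat = g["lat"].to_numpy(dtype=float)
        lon = g["lon"].to_numpy(dtype=float)
        t = g["time"].to_numpy()
        n = len(g)
        i = 0
        while i < n:
            if s[i] != "S":
                i += 1
                continue
            j = i
            while j < n and s[j] == "S":
                j += 1
            dist = float(haversine_km(lat[i:j - 1], lon[i:j - 1], lat[i + 1:j], lon[i + 1:j]).sum()) if j - i > 1 else 0.0
            rows.append(
                {
                    "buoy_id": bid,
                    "start_time": t[i],
                    "end_time": t[j - 1],
                    "start_lat": lat[i],
                    "start_lon": lon[i],
                    "end_lat": lat[j - 1],
                    "end_lon": lon[j - 1],
                    "n_positions": j - i,
                    "duration_days": float((t[j - 1] - t[i]) / np.timedelta64(1, "s")) / 86400.0,
                    "distance_km": dist,
                    "end_event": "retrieval" if j < n else "track_end",
                }
            )
            i = j
    return pd.DataFrame(
        rows,
        columns=[
            "buoy_id", "start_time", "end_time", "start_lat", "start_lon",
            "end_lat", "end_lon", "n_positions", "duration_days", "distance_km",
            "end_event",
        ],
    )


def trajectory_summary(
    trajectories: pd.DataFrame,
    value: str = "duration_days",
    group_by: str | None = None,
) -> pd.DataFrame:
    """Mean, sample SD, SE (= SD / sqrt(n)) and n, overall or per group.

    ``group_by="month"`` groups by the month the trajectory *ends* (the
    recapture month). Groups with a single trajectory get NaN SD/SE.
    """
    if trajectories.empty:
        raise ValueError("no trajectories")
    df = trajectories.copy()
    if group_by is None:
        df["_g"] = "all"
    elif group_by == "month":
        df["_g"] = pd.DatetimeIndex(df["end_time"]).month
    elif group_by == "year":
        df["_g"] = pd.DatetimeIndex(df["start_time"]).year
    else:
        df["_g"] = df[group_by]
    rows = []
    for g, part in df.groupby("_g"):
        x = part[value].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else np.nan
        rows.append(
            {
                "group": g,
                "n": x.size,
                "mean": float(x.mean()),
                "sd": sd,
                "se": sd / np.sqrt(x.size) if x.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def predicted_fishing_sets(classified: pd.DataFrame, state_col: str = "state") -> pd.DataFrame:
    """End points of at-sea runs that are followed by an on-board fix.

    These S->B transitions are candidate dFAD fishing-set (retrieval)
    positions; runs ending at the track end are excluded.
    """
    traj = extract_sea_trajectories(classified, state_col)
    sets = traj.loc[traj["end_event"] == "retrieval"]
    return sets[["buoy_id", "end_time", "end_lat", "end_lon"]].rename(
        columns={"end_time": "time", "end_lat": "lat", "end_lon": "lon"}
    ).reset_index(drop=True)


def grid_density(points: pd.DataFrame, resolution: float = 1.0) -> pd.DataFrame:
    """Point counts on half-open [k, k+1) cells keyed by their SW corner."""
    cell_lat = np.floor(points["lat"].to_numpy(dtype=float) / resolution).astype(int)
    cell_lon = np.floor(points["lon"].to_numpy(dtype=float) / resolution).astype(int)
    out = (
        pd.DataFrame({"cell_lat": cell_lat, "cell_lon": cell_lon})
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["cell_lat", "cell_lon"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def _bandwidth_nrd(x: np.ndarray) -> float:
    """R's rule-of-thumb bandwidth (bandwidth.nrd): 4 * 1.06 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = np.std(x, ddof=1)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    spread = min(sd, (q3 - q1) / 1.34) if (q3 - q1) > 0 else sd
    if spread == 0:
        spread = max(abs(x[0]), 1.0) * 1e-3  # bandwidth floor for degenerate axes
    return 4.0 * 1.06 * spread * x.size ** (-1 / 5)


def smooth_density(
    points: pd.DataFrame,
    bandwidth: tuple[float, float] | None = None,
    gridsize: int = 60,
    extent: tuple[float, float, float, float] | None = None,
):
    """kde2d-style product Gaussian kernel density on a regular grid.

    Bandwidths default to the normal reference rule per axis (quarter of
    which is the Gaussian sigma, as in MASS::kde2d). Returns (grid_lon,
    grid_lat, density) with density integrating to ~1 over the grid.
    """
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    if lon.size < 2:
        raise ValueError("need at least 2 points")
    if bandwidth is None:
        h = (_bandwidth_nrd(lon), _bandwidth_nrd(lat))
    else:
        h = bandwidth
    sx, sy = h[0] / 4.0, h[1] / 4.0  # kde2d uses h/4 as the Gaussian sd
    if extent is None:
        extent = (
            lon.min() - 3 * sx * 4, lon.max() + 3 * sx * 4,
            lat.min() - 3 * sy * 4, lat.max() + 3 * sy * 4,
        )
    gx = np.linspace(extent[0], extent[1], gridsize)
    gy = np.linspace(extent[2], extent[3], gridsize)
    zx = stats.norm.pdf((gx[:, None] - lon[None, :]) / sx) / sx
    zy = stats.norm.pdf((gy[:, None] - lat[None, :]) / sy) / sy
    dens = zy @ zx.T / lon.size  # (gridsize_y, gridsize_x)
    return gx, gy, dens


def compare_set_maps(
    observed: pd.DataFrame, predicted: pd.DataFrame, resolution: float = 1.0
) -> tuple[float, int]:
    """Spearman correlation of observed and predicted set densities.

    Computed over the union of cells occupied by at least one observed or
    predicted set; a cell missing from one map counts 0 there. Returns
    (rho, n_cells); with fewer than 3 occupied cells rho is NaN.
    """
    if observed.empty or predicted.empty:
        raise ValueError("both point sets must be non-empty")
    obs = grid_density(observed, resolution).set_index(["cell_lat", "cell_lon"])["count"]
    pre = grid_density(predicted, resolution).set_index(["cell_lat", "cell_lon"])["count"]
    cells = obs.index.union(pre.index)
    if len(cells) < 3:
        return np.nan, len(cells)
    o = obs.reindex(cells, fill_value=0).to_numpy(dtype=float)
    p = pre.reindex(cells, fill_value=0).to_numpy(dtype=float)
    if np.array_equal(o, p):  # identical maps: perfect rank agreement
        return 1.0, len(cells)
    if np.all(o == o[0]) or np.all(p == p[0]):  # constant vector: rho undefined
        return np.nan, len(cells)
    rho = stats.spearmanr(o, p).statistic
    return float(rho), len(cells)


def detect_beachings(
    raw: pd.DataFrame,
    ports: np.ndarray,
    coastline: np.ndarray,
    cfg: BeachingConfig | None = None,
    trajectories: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Beaching events from repeated identical raw positions.

    Works on the raw (pre-doubled-removal) stream: maximal runs of at least
    ``min_repeats`` identical consecutive fixes of a buoy are candidate
    events; runs within ``port_exclusion_km`` of a port are discarded as
    anchorages, and the ``within_coast`` flag marks events within
    ``coast_max_km`` of the coastline (the final filter; events are returned
    with the flag so both counts can be reported). If classified
    ``trajectories`` are supplied, each event is linked to the deployment
    (start position) of the at-sea trajectory containing it.
    """
    cfg = cfg or BeachingConfig()
    ports = np.asarray(ports, dtype=float)
    df = raw.sort_values(["buoy_id", "time"], kind="stable").reset_index(drop=True)
    rows = []
    tol = cfg.position_tolerance_deg
    for bid, g in df.groupby("buoy_id", sort=False):
        lat = g["lat"].to_numpy(dtype=float)
        lon = g["lon"].to_numpy(dtype=float)
        t = g["time"].to_numpy()
        n = len(g)
        i = 0
        while i < n:
            j = i + 1
            while (
                j < n
                and abs(lat[j] - lat[i]) <= tol
                and abs(lon[j] - lon[i]) <= tol
            ):
                j += 1
            if j - i >= cfg.min_repeats:
                rows.append(
                    {
                        "buoy_id": bid,
                        "lat": lat[i],
                        "lon": lon[i],
                        "first_time": t[i],
                        "last_time": t[j - 1],
                        "n_repeats": j - i,
                    }
                )
            i = j
    events = pd.DataFrame(
        rows, columns=["buoy_id", "lat", "lon", "first_time", "last_time", "n_repeats"]
    )
    if events.empty:
        events["port_dist_km"] = events["coast_dist_km"] = []
        events["within_coast"] = []
        return events
    events["port_dist_km"] = haversine_km(
        events["lat"].to_numpy()[:, None], events["lon"].to_numpy()[:, None],
        ports[None, :, 0], ports[None, :, 1],
    ).min(axis=1)
    events = events.loc[events["port_dist_km"] > cfg.port_exclusion_km].reset_index(drop=True)
    if events.empty:
        events["coast_dist_km"] = []
        events["within_coast"] = []
        return events
    events["coast_dist_km"] = distance_to_polyline_km(
        events["lat"].to_numpy(), events["lon"].to_numpy(), coastline
    )
    events["within_coast"] = events["coast_dist_km"] <= cfg.coast_max_km
    if trajectories is not None and not trajectories.empty:
        dep_lat, dep_lon = [], []
        for _, ev in events.iterrows():
            tr = trajectories.loc[
                (trajectories["buoy_id"] == ev["buoy_id"])
                & (trajectories["start_time"] <= ev["first_time"])
                & (trajectories["end_time"] >= ev["first_time"])
            ]
            if len(tr):
                dep_lat.append(tr.iloc[0]["start_lat"])
                dep_lon.append(tr.iloc[0]["start_lon"])
            else:
                dep_lat.append(np.nan)
                dep_lon.append(np.nan)
        events["deploy_lat"] = dep_lat
        events["deploy_lon"] = dep_lon
    return events


def fishing_grounds(sets: pd.DataFrame, period: tuple | None = None) -> set[tuple[int, int]]:
    """1-degree cells containing at least one fishing set (optionally in a period)."""
    df = sets
    if period is not None:
        t0, t1 = period
        df = df.loc[(df["time"] >= t0) & (df["time"] <= t1)]
    if df.empty:
        import warnings

        warnings.warn("no fishing sets: empty fishing ground")
        return set()
    cells = zip(
        np.floor(df["lat"].to_numpy(dtype=float)).astype(int),
        np.floor(df["lon"].to_numpy(dtype=float)).astype(int),
    )
    return set(cells)


def ineffective_effort(
    classified: pd.DataFrame,
    ground_cells: set[tuple[int, int]],
    state_col: str = "state",
    thresholds=(0.5,),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drift time outside fishing grounds, per at-sea trajectory.

    Each inter-fix interval of a trajectory is attributed to the 1-degree
    cell of its *starting* fix. Returns (effort records, per-cell density of
    outside positions, share of trajectories with outside fraction above
    each threshold). Single-fix trajectories carry zero duration and are
    excluded from the shares.
    """
    df = classified.sort_values(["buoy_id", "time"], kind="stable").reset_index(drop=True)
    effort_rows = []
    outside_points = []
    for bid, g in df.groupby("buoy_id", sort=False):
        s = g[state_col].to_numpy()
        lat = g["lat"].to_numpy(dtype=float)
        lon = g["lon"].to_numpy(dtype=float)
        t = g["time"].to_numpy()
        n = len(g)
        i = 0
        traj_idx = 0
        while i < n:
            if s[i] != "S":
                i += 1
                continue
            j = i
            while j < n and s[j] == "S":
                j += 1
            total = 0.0
            outside = 0.0
            for k in range(i, j - 1):
                dt_days = float((t[k + 1] - t[k]) / np.timedelta64(1, "s")) / 86400.0
                cell = (int(np.floor(lat[k])), int(np.floor(lon[k])))
                total += dt_days
                if cell not in ground_cells:
                    outside += dt_days
                    outside_points.append({"buoy_id": bid, "lat": lat[k], "lon": lon[k]})
            effort_rows.append(
                {
                    "buoy_id": bid,
                    "trajectory": traj_idx,
                    "total_days": total,
                    "outside_days": outside,
                    "fraction_outside": outside / total if total > 0 else np.nan,
                }
            )
            traj_idx += 1
            i = j
    effort = pd.DataFrame(
        effort_rows,
        columns=["buoy_id", "trajectory", "total_days", "outside_days", "fraction_outside"],
    )
    out_pts = pd.DataFrame(outside_points, columns=["buoy_id", "lat", "lon"])
    density = grid_density(out_pts) if not out_pts.empty else pd.DataFrame(
        columns=["cell_lat", "cell_lon", "count"]
    )
    valid = effort.loc[effort["total_days"] > 0, "fraction_outside"]
    shares = {
        thr: float((valid > thr).mean()) if len(valid) else np.nan for thr in thresholds
    }
    return effort, density, shares
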