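"""Synthetic fleet world: vessels, drifting GPS buoys, and ground truth.

Emulates the statistical structure of a tropical purse-seine fleet's
dFAD-tracking data: GPS buoys alternate "on board" (B) phases, during which
they ride a fishing vessel and their fixes coincide with the vessel's hourly
VMS positions, and "at sea" (S) phases, during which they drift slowly on a
correlated random walk. Fixes are emitted at irregular timesteps (1 h to
1 d), sea-surface temperature follows a smooth latitudinal gradient with
noise, and the raw stream can be salted with the classic data artifacts:
same-hour duplicate fixes, "doubled" identical consecutive fixes, and
invalid rows. Some drift phases terminate by beaching on the coastline,
emitted as repeats of the identical recorded coordinates.

Vessels and buoys are co-simulated on an hourly clock: a vessel deploys a
buoy at the end of a fishing set and later sails back to the buoy's drifted
position to retrieve it, so tracks contain no physically impossible jumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import destination_point, haversine_km, initial_bearing, normalize_lon

T0 = pd.Timestamp("2010-01-01 00:00:00")


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic world and fleet.

    Speeds in m/s, durations in the stated units. ``drift_speed_max`` must be
    strictly below the cruising range so that the speed classes overlap only
    through fishing-set periods (the low-vessel-speed confusion that motivates
    multivariate classifiers over a plain speed filter).
    """

    n_vessels: int = 5
    n_buoys: int = 50
    onboard_speed_range: tuple[float, float] = (2.0, 7.0)
    set_speed_range: tuple[float, float] = (0.0, 0.5)
    drift_speed_max: float = 0.8
    drift_persistence: float = 0.85
    timestep_choices: tuple[int, ...] = (1, 6, 12, 24)
    timestep_probs: tuple[float, ...] = (0.2, 0.3, 0.25, 0.25)
    p_duplicate: float = 0.02
    p_doubled: float = 0.01
    p_invalid: float = 0.005
    p_beach: float = 0.10
    p_offshore_stop: float = 0.05
    sst_noise_sd: float = 0.2
    seed: int = 0
    # world extent and ports
    bbox: tuple[float, float, float, float] = (-15.0, 10.0, 40.0, 65.0)  # lat0, lat1, lon0, lon1
    n_ports: int = 2
    # fleet schedule
    horizon_days: int = 45
    drift_days_range: tuple[float, float] = (5.0, 16.0)
    cycles_range: tuple[int, int] = (1, 3)
    set_hours_range: tuple[int, int] = (2, 5)

    def __post_init__(self) -> None:
        lat0, lat1, lon0, lon1 = self.bbox
        if lat1 <= lat0 or lon1 <= lon0:
            raise ConfigurationError("degenerate bbox (zero area)")
        if not (self.drift_speed_max < min(self.onboard_speed_range)):
            raise ConfigurationError("drift_speed_max must be strictly below cruising speeds")
        for name in ("p_duplicate", "p_doubled", "p_invalid", "p_beach", "p_offshore_stop"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.drift_persistence < 1.0:
            raise ConfigurationError("drift_persistence must be in [0, 1)")
        if len(self.timestep_probs) != len(self.timestep_choices):
            raise ConfigurationError("timestep_probs must match timestep_choices")


@dataclass
class World:
    """Ports, a coastline polyline and 1-degree fishing-ground cells."""

    ports: list[tuple[str, float, float]]  # (name, lat, lon)
    coastline: np.ndarray  # (n, 2) lat/lon vertices
    ground_cells: set[tuple[int, int]]  # SW-corner (lat, lon) of 1x1 deg cells
    bbox: tuple[float, float, float, float]

    @property
    def port_array(self) -> np.ndarray:
        return np.array([[lat, lon] for _, lat, lon in self.ports], dtype=float)


def generate_world(config: ScenarioConfig) -> World:
    """Build a deterministic world from the scenario seed.

    The fishing grounds form a contiguous block of 1-degree cells in the
    central bbox with a margin of at least two non-ground cell rows on every
    side; the coastline runs near the western edge, outside the grounds, with
    the ports sitting on it.
    """
    lat0, lat1, lon0, lon1 = config.bbox
    if lat1 - lat0 < 10 or lon1 - lon0 < 10:
        raise ConfigurationError("bbox must span at least 10 x 10 degrees")
    if config.n_ports < 1:
        raise ConfigurationError("need at least one port")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    lats = np.arange(lat0, lat1 + 1e-9, 0.25)
    wiggle = 0.6 * np.sin(2 * np.pi * lats / 15.0) + rng.normal(0.0, 0.05, size=lats.size)
    lons = lon0 + 1.5 + wiggle
    coastline = np.column_stack([lats, lons])

    port_idx = np.linspace(0.2, 0.8, config.n_ports)
    ports = []
    for k, f in enumerate(port_idx):
        i = int(round(f * (lats.size - 1)))
        ports.append((f"port_{k}", float(coastline[i, 0]), float(coastline[i, 1])))

    ground = {
        (ilat, ilon)
        for ilat in range(int(math.floor(lat0)) + 4, int(math.floor(lat1)) - 4)
        for ilon in range(int(math.floor(lon0)) + 6, int(math.floor(lon1)) - 4)
    }
    return World(ports=ports, coastline=coastline, ground_cells=ground, bbox=config.bbox)


def _sst(lat: float, cfg: ScenarioConfig, rng: np.random.Generator) -> float:
    lat0, lat1, _, _ = cfg.bbox
    base = 27.0 - 0.10 * (lat - 0.5 * (lat0 + lat1))
    return base + rng.normal(0.0, cfg.sst_noise_sd)


def _wrap180(x: float) -> float:
    return (x + 180.0) % 360.0 - 180.0


# --------------------------------------------------------------------------
# standalone vessel trip (no buoys) -- VMS emulation
# --------------------------------------------------------------------------

def simulate_vessel_trip(
    world: World,
    config: ScenarioConfig,
    vessel_id: str,
    trip_days: int = 14,
    n_waypoints: int = 3,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly VMS track for one port-to-port trip with fishing sets.

    The vessel leaves a port, cruises between random waypoints in the fishing
    grounds at speeds drawn from ``onboard_speed_range`` (one draw per hour),
    performs a slow fishing set at each waypoint, and returns to the port.
    Returns (track, sets); ``track`` has one row per hour with a ``mode``
    column in {port, cruise, arrive, set}.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    _, plat, plon = world.ports[rng.integers(len(world.ports))]
    glat = sorted({c[0] for c in world.ground_cells})
    glon = sorted({c[1] for c in world.ground_cells})

    lat, lon = plat, plon
    rows = [(0, lat, lon, "port")]
    sets = []
    h = 1
    targets = [
        (rng.uniform(glat[0], glat[-1] + 1), rng.uniform(glon[0], glon[-1] + 1))
        for _ in range(n_waypoints)
    ] + [(plat, plon)]
    max_h = trip_days * 24
    for i, (tlat, tlon) in enumerate(targets):
        while h < max_h:
            v = rng.uniform(*config.onboard_speed_range)
            step = v * 3.6  # km per hour
            d = haversine_km(lat, lon, tlat, tlon)
            if d <= step:
                lat, lon = tlat, tlon
                rows.append((h, lat, lon, "arrive"))
                h += 1
                break
            brg = initial_bearing(lat, lon, tlat, tlon)
            lat, lon = destination_point(lat, lon, brg, step)
            rows.append((h, lat, lon, "cruise"))
            h += 1
        if i < n_waypoints and h < max_h:
            sets.append((vessel_id, h, lat, lon))
            for _ in range(int(rng.integers(*config.set_hours_range))):
                v = rng.uniform(*config.set_speed_range)
                lat, lon = destination_point(lat, lon, rng.uniform(0, 360), v * 3.6)
                rows.append((h, lat, lon, "set"))
                h += 1
    rows.append((h, plat, plon, "port"))

    track = pd.DataFrame(rows, columns=["hour", "lat", "lon", "mode"])
    track["vessel_id"] = vessel_id
    track["time"] = T0 + pd.to_timedelta(track.pop("hour"), unit="h")
    track = track[["vessel_id", "time", "lat", "lon", "mode"]]
    sets_df = pd.DataFrame(sets, columns=["vessel_id", "hour", "lat", "lon"])
    sets_df["time"] = T0 + pd.to_timedelta(sets_df.pop("hour"), unit="h")
    sets_df["kind"] = "free"
    return track, sets_df


# --------------------------------------------------------------------------
# fleet co-simulation
# --------------------------------------------------------------------------

@dataclass
class _Buoy:
    buoy_id: str
    vessel_id: str
    cycles_total: int
    status: str = "awaiting"  # awaiting | drifting | beaching | beached_hold | retired
    deploy_count: int = 0
    lat: float = np.nan
    lon: float = np.nan
    heading: float = 0.0
    heading_dev: float = 0.0
    phase_heading: float = 0.0
    ripe_hour: int = 0
    pending_beach: bool = False
    beach_target: tuple[float, float] | None = None
    beach_hour: int | None = None
    hold_start: int | None = None
    hold_end: int | None = None
    holds: list[tuple[int, int]] = field(default_factory=list)
    drift: list[tuple[int, float, float]] = field(default_factory=list)
    events: list[tuple[str, int, float, float]] = field(default_factory=list)
    end_hour: int | None = None


@dataclass
class _Vessel:
    vessel_id: str
    port: tuple[float, float]
    depart: int
    lat: np.ndarray
    lon: np.ndarray
    mode: np.ndarray
    task: tuple | None = None
    last_deploy_hour: int = -999


@dataclass
class FleetData:
    """Joint output of one synthetic scenario."""

    vms: pd.DataFrame           # vessel_id, time, lat, lon, mode
    buoys: pd.DataFrame         # buoy_id, vessel_id, time, lat, lon, sst, state, artifact
    events: pd.DataFrame        # buoy_id, event, time, lat, lon
    sets: pd.DataFrame          # vessel_id, buoy_id, time, lat, lon, kind
    world: World
    config: ScenarioConfig


def _pick_beach_target(world: World, rng: np.random.Generator) -> tuple[float, float]:
    """Coastline vertex > 10 km from every port (beaching-detector safe)."""
    ports = world.port_array
    for _ in range(200):
        i = rng.integers(world.coastline.shape[0])
        lat, lon = world.coastline[i]
        if haversine_km(lat, lon, ports[:, 0], ports[:, 1]).min() > 12.0:
            return float(lat), float(lon)
    raise GenerationError("could not find a beaching point away from ports")


def simulate_fleet(world: World, config: ScenarioConfig) -> FleetData:
    """Co-simulate vessels and buoys over the scenario horizon.

    Deterministic for a given config (single seeded RNG, fixed iteration
    order). Raises :class:`GenerationError` if a buoy cannot be deployed.
    """
    if config.n_vessels < 1 or config.n_buoys < 1:
        raise GenerationError("need at least one vessel and one buoy")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    H = config.horizon_days * 24
    glat = sorted({c[0] for c in world.ground_cells})
    glon = sorted({c[1] for c in world.ground_cells})

    vessels: list[_Vessel] = []
    for i in range(config.n_vessels):
        name, plat, plon = world.ports[i % len(world.ports)]
        v = _Vessel(
            vessel_id=f"vessel_{i:02d}",
            port=(plat, plon),
            depart=int(rng.integers(12, 37)),
            lat=np.full(H + 1, plat),
            lon=np.full(H + 1, plon),
            mode=np.full(H + 1, "port", dtype=object),
        )
        vessels.append(v)

    buoys: dict[str, _Buoy] = {}
    vessel_buoys: dict[str, list[_Buoy]] = {v.vessel_id: [] for v in vessels}
    for j in range(config.n_buoys):
        v = vessels[j % config.n_vessels]
        b = _Buoy(
            buoy_id=f"buoy_{j:03d}",
            vessel_id=v.vessel_id,
            cycles_total=int(rng.integers(config.cycles_range[0], config.cycles_range[1] + 1)),
        )
        buoys[b.buoy_id] = b
        vessel_buoys[v.vessel_id].append(b)

    sets: list[tuple[str, str, int, float, float, str]] = []
    sigma_turn = 18.0

    def step_buoy(b: _Buoy, h: int) -> None:
        if b.status not in ("drifting", "beaching"):
            return
        if b.hold_start is not None and b.hold_start <= h < b.hold_end:
            if h == b.hold_start:
                b.events.append(("offshore_stop", h, b.lat, b.lon))
            b.drift.append((h, b.lat, b.lon))
            return
        if b.status == "beaching":
            speed = rng.uniform(0.75, 1.0) * config.drift_speed_max
            tgt = initial_bearing(b.lat, b.lon, *b.beach_target)
            step = speed * 3.6
            d = haversine_km(b.lat, b.lon, *b.beach_target)
            if d <= step:
                b.lat, b.lon = b.beach_target
                b.status = "beached_hold"
                b.beach_hour = h
                b.events.append(("beaching", h, b.lat, b.lon))
                b.drift.append((h, b.lat, b.lon))
                return
            dev = _wrap180(b.heading - tgt)
            dev = config.drift_persistence * dev + rng.normal(0.0, 10.0)
            b.heading = tgt + dev
        else:
            speed = rng.uniform(0.0, config.drift_speed_max)
            b.heading_dev = config.drift_persistence * b.heading_dev + rng.normal(0.0, sigma_turn)
            b.heading = b.phase_heading + b.heading_dev
        b.lat, b.lon = destination_point(b.lat, b.lon, b.heading, speed * 3.6)
        b.drift.append((h, b.lat, b.lon))

    def deploy(b: _Buoy, v: _Vessel, h: int) -> None:
        b.deploy_count += 1
        b.lat, b.lon = float(v.lat[h]), float(v.lon[h])
        b.phase_heading = rng.uniform(0.0, 360.0)
        b.heading = b.phase_heading
        b.heading_dev = 0.0
        b.hold_start = b.hold_end = None
        drift_days = rng.uniform(*config.drift_days_range)
        b.ripe_hour = h + int(drift_days * 24)
        if b.pending_beach:
            b.status = "beaching"
            b.beach_target = _pick_beach_target(world, rng)
        else:
            b.status = "drifting"
            if rng.random() < config.p_offshore_stop:
                hold_start = h + int(rng.uniform(0.3, 0.7) * drift_days * 24)
                hold_end = hold_start + int(rng.uniform(24, 42))
                if hold_end < H - 24:  # a stop truncated by the horizon is no plant
                    b.hold_start, b.hold_end = hold_start, hold_end
                    b.holds.append((hold_start, hold_end))
        b.events.append(("deployment", h, b.lat, b.lon))

    def deployment_waypoint(b: _Buoy, v: _Vessel, h: int) -> tuple[float, float]:
        # beaching is decided per at-sea phase, at planning time, so the
        # vessel can stage the deployment nearer the western grounds edge
        b.pending_beach = rng.random() < config.p_beach
        if b.pending_beach:
            return (rng.uniform(glat[0] + 1, glat[-1]), rng.uniform(glon[0], glon[0] + 3))
        if h - v.last_deploy_hour < 48:
            lat = float(np.clip(v.lat[h] + rng.uniform(-1.5, 1.5), glat[0], glat[-1] + 1))
            lon = float(np.clip(v.lon[h] + rng.uniform(-1.5, 1.5), glon[0], glon[-1] + 1))
            return lat, lon
        return (rng.uniform(glat[0], glat[-1] + 1), rng.uniform(glon[0], glon[-1] + 1))

    def choose_task(v: _Vessel, h: int) -> tuple:
        plat, plon = v.port
        d_home = haversine_km(v.lat[h - 1], v.lon[h - 1], plat, plon)
        hours_home = d_home / (config.onboard_speed_range[0] * 3.6)
        if H - h <= hours_home + 8:
            return ("to_port",)
        # buoys waiting on deck are redeployed before new pursuits start
        awaiting = [b for b in vessel_buoys[v.vessel_id] if b.status == "awaiting"]
        if awaiting and h < H - 96:
            b = awaiting[0]
            return ("cruise", deployment_waypoint(b, v, h - 1), ("deploy", b.buoy_id))
        ripe = [
            b for b in vessel_buoys[v.vessel_id]
            if b.status == "drifting" and h >= b.ripe_hour
        ]
        if ripe and h < H - 72:
            d = [haversine_km(v.lat[h - 1], v.lon[h - 1], b.lat, b.lon) for b in ripe]
            return ("pursuit", ripe[int(np.argmin(d))].buoy_id)
        # wander inside the grounds
        wp = (rng.uniform(glat[0], glat[-1] + 1), rng.uniform(glon[0], glon[-1] + 1))
        return ("cruise", wp, None)

    for h in range(1, H + 1):
        for b in buoys.values():
            step_buoy(b, h)
        for v in vessels:
            if h < v.depart:
                v.mode[h] = "port"
                continue
            if v.task is None:
                v.task = choose_task(v, h)
            kind = v.task[0]
            if kind in ("cruise", "to_port", "pursuit"):
                if kind == "pursuit":
                    b = buoys[v.task[1]]
                    if b.status != "drifting":  # lost to horizon edge cases
                        v.task = None
                        v.lat[h], v.lon[h], v.mode[h] = v.lat[h - 1], v.lon[h - 1], "cruise"
                        continue
                    tlat, tlon = b.lat, b.lon
                elif kind == "to_port":
                    tlat, tlon = v.port
                else:
                    tlat, tlon = v.task[1]
                sp = rng.uniform(*config.onboard_speed_range)
                step = sp * 3.6
                d = haversine_km(v.lat[h - 1], v.lon[h - 1], tlat, tlon)
                if d <= step:
                    v.lat[h], v.lon[h] = tlat, tlon
                    v.mode[h] = "arrive"
                    if kind == "pursuit":
                        b.status = "awaiting" if b.deploy_count < b.cycles_total else "retired"
                        b.events.append(("retrieval", h, tlat, tlon))
                        b.drift.append((h, tlat, tlon))  # position at pickup hour
                        # the logbook set is recorded at the FAD's last
                        # reported drift position (one hour before pickup)
                        slat, slon = next(
                            ((la, lo) for hh, la, lo in reversed(b.drift) if hh == h - 1),
                            (tlat, tlon),
                        )
                        sets.append((v.vessel_id, b.buoy_id, h, slat, slon, "retrieval"))
                        v.task = ("set", int(rng.integers(*config.set_hours_range)), None)
                    elif kind == "to_port":
                        v.mode[h] = "port"
                        v.task = ("port_idle",)
                    else:
                        nxt = v.task[2]
                        if nxt is not None and nxt[0] == "deploy":
                            sets.append((v.vessel_id, nxt[1], h, tlat, tlon, "deployment"))
                            v.task = ("set", int(rng.integers(*config.set_hours_range)), nxt[1])
                        else:
                            v.task = None
                else:
                    brg = initial_bearing(v.lat[h - 1], v.lon[h - 1], tlat, tlon)
                    v.lat[h], v.lon[h] = destination_point(v.lat[h - 1], v.lon[h - 1], brg, step)
                    v.mode[h] = "pursuit" if kind == "pursuit" else "cruise"
            elif kind == "set":
                sp = rng.uniform(*config.set_speed_range)
                v.lat[h], v.lon[h] = destination_point(
                    v.lat[h - 1], v.lon[h - 1], rng.uniform(0, 360), sp * 3.6
                )
                v.mode[h] = "set"
                hours_left, payload = v.task[1] - 1, v.task[2]
                if hours_left <= 0:
                    if payload is not None:
                        deploy(buoys[payload], v, h)
                        v.last_deploy_hour = h
                    v.task = None
                else:
                    v.task = ("set", hours_left, payload)
            elif kind == "port_idle":
                v.lat[h], v.lon[h] = v.port
                v.mode[h] = "port"

    return _assemble(world, config, rng, vessels, buoys, sets, H)


def _assemble(world, config, rng, vessels, buoys, sets, H) -> FleetData:
    """Reconstruct onboard segments, emission schedules and truth tables."""
    vms_frames = []
    for v in vessels:
        df = pd.DataFrame(
            {
                "vessel_id": v.vessel_id,
                "time": T0 + pd.to_timedelta(np.arange(H + 1), unit="h"),
                "lat": v.lat,
                "lon": v.lon,
                "mode": v.mode,
            }
        )
        vms_frames.append(df)
    vms = pd.concat(vms_frames, ignore_index=True)
    vmap = {v.vessel_id: v for v in vessels}

    pos_rows = []
    event_rows = []
    for bid in sorted(buoys):
        b = buoys[bid]
        if b.deploy_count == 0:
            continue  # never left the vessel: no track
        v = vmap[b.vessel_id]
        drift_pos = dict((h, (la, lo)) for h, la, lo in b.drift)
        deploys = [h for e, h, _, _ in b.events if e == "deployment"]
        retrievals = [h for e, h, _, _ in b.events if e == "retrieval"]

        activation = max(0, deploys[0] - int(rng.uniform(24, 84)))
        if b.status == "beached_hold":
            n_rep = 3 + int(rng.integers(0, 3))
            end_hour = None  # resolved during emission walk
        else:
            n_rep = 0
            if b.status == "retired":
                # stored on board: a few trailing fixes, then switched off
                end_hour = min(H, retrievals[-1] + int(rng.uniform(6, 24)))
            else:
                end_hour = H  # still drifting at horizon

        def state_at(h: int) -> str:
            # B before first deployment, between retrieval and redeployment,
            # and after final retrieval; S while drifting (incl. beached hold)
            last_dep = max([d for d in deploys if d <= h], default=None)
            last_ret = max([r for r in retrievals if r <= h], default=None)
            if last_dep is None:
                return "B"
            if last_ret is not None and last_ret >= last_dep:
                return "B"
            return "S"

        def position_at(h: int) -> tuple[float, float]:
            if h in drift_pos:
                return drift_pos[h]
            if b.status == "beached_hold" and h >= b.beach_hour:
                return b.beach_target
            return float(v.lat[h]), float(v.lon[h])

        h = activation
        emitted_beach = 0
        while True:
            beach_holding = b.status == "beached_hold" and h >= b.beach_hour
            if h > H and not beach_holding:
                break
            st = state_at(h)
            lat, lon = position_at(h)
            pos_rows.append((bid, b.vessel_id, h, lat, lon, _sst(lat, config, rng), st))
            if beach_holding:
                # stranded: repeat the identical recorded coordinates
                emitted_beach += 1
                if emitted_beach >= n_rep:
                    break
                h += 6
                continue
            if end_hour is not None and h >= end_hour:
                break
            in_hold = st == "S" and any(hs <= h < he for hs, he in b.holds)
            next_ret = min([r for r in retrievals if r > h], default=None)
            if st == "B":
                if v.mode[h] == "set":
                    dt = 1
                elif v.mode[h] == "port":
                    dt = int(rng.choice([6, 12]))
                else:
                    dt = int(rng.choice([6, 12, 24], p=[0.3, 0.4, 0.3]))
            elif in_hold:
                dt = 6
            elif next_ret is not None and next_ret - h <= 12:
                dt = 1
            else:
                dt = int(rng.choice(config.timestep_choices, p=config.timestep_probs))
            # never step over the pre-retrieval window: the skipper switches to
            # hourly monitoring for the final approach
            if st == "S" and next_ret is not None and h + dt > next_ret - 12:
                dt = max(1, next_ret - 12 - h)
            # land on the start of an offshore hold so the repeat run is emitted
            if st == "S":
                for hs, _ in b.holds:
                    if h < hs < h + dt:
                        dt = hs - h
                        break
            # dense monitoring right after pickup, so the onboard interval
            # between retrieval and a possible redeployment is never skipped
            if st == "S" and h in retrievals:
                dt = 1
            h += dt

        last = pos_rows[-1]
        b.events.append(("track_end", last[2], last[3], last[4]))
        for e, eh, elat, elon in b.events:
            event_rows.append((bid, e, eh, elat, elon))

    buoys_df = pd.DataFrame(
        pos_rows, columns=["buoy_id", "vessel_id", "hour", "lat", "lon", "sst", "state"]
    )
    if buoys_df.empty:
        raise GenerationError("no buoy was ever deployed; extend the horizon")
    buoys_df["time"] = T0 + pd.to_timedelta(buoys_df.pop("hour"), unit="h")
    buoys_df["artifact"] = "none"
    buoys_df = buoys_df[
        ["buoy_id", "vessel_id", "time", "lat", "lon", "sst", "state", "artifact"]
    ].sort_values(["buoy_id", "time"], kind="stable").reset_index(drop=True)

    events_df = pd.DataFrame(event_rows, columns=["buoy_id", "event", "hour", "lat", "lon"])
    events_df["time"] = T0 + pd.to_timedelta(events_df.pop("hour"), unit="h")
    events_df = events_df[["buoy_id", "event", "time", "lat", "lon"]].sort_values(
        ["buoy_id", "time"], kind="stable"
    ).reset_index(drop=True)

    sets_df = pd.DataFrame(
        sets, columns=["vessel_id", "buoy_id", "hour", "lat", "lon", "kind"]
    )
    sets_df["time"] = T0 + pd.to_timedelta(sets_df.pop("hour"), unit="h")
    sets_df = sets_df[["vessel_id", "buoy_id", "time", "lat", "lon", "kind"]]

    return FleetData(vms=vms, buoys=buoys_df, events=events_df, sets=sets_df,
                     world=world, config=config)


# --------------------------------------------------------------------------
# artifact injection
# --------------------------------------------------------------------------

def inject_artifacts(
    positions: pd.DataFrame, config: ScenarioConfig, seed: int | None = None
) -> pd.DataFrame:
    """Salt a clean emission stream with raw-data artifacts.

    Adds, per input row and independently: a same-hour duplicate fix at rate
    ``p_duplicate`` (same timestamp, offset position), a "doubled" fix at rate
    ``p_doubled`` (identical coordinates one hour later), and an invalid row at
    rate ``p_invalid`` (missing or out-of-range coordinates). Original rows are
    retained untouched; injected rows are flagged in the ``artifact`` column.
    """
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    out = [positions]
    n = len(positions)
    if n == 0:
        return positions.copy()

    dup_mask = rng.random(n) < config.p_duplicate
    if dup_mask.any():
        dup = positions.loc[dup_mask].copy()
        dup["lat"] = dup["lat"] + rng.uniform(-0.05, 0.05, size=len(dup))
        dup["lon"] = normalize_lon(dup["lon"] + rng.uniform(-0.05, 0.05, size=len(dup)))
        dup["artifact"] = "duplicate"
        out.append(dup)

    dbl_mask = rng.random(n) < config.p_doubled
    if dbl_mask.any():
        dbl = positions.loc[dbl_mask].copy()
        dbl["time"] = dbl["time"] + pd.Timedelta(hours=1)
        dbl["artifact"] = "doubled"
        out.append(dbl)

    inv_mask = rng.random(n) < config.p_invalid
    if inv_mask.any():
        inv = positions.loc[inv_mask].copy()
        bad_kind = rng.random(len(inv)) < 0.5
        inv.loc[bad_kind, "lat"] = np.nan
        inv.loc[~bad_kind, "lon"] = 999.0
        inv["artifact"] = "invalid"
        out.append(inv)

    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["buoy_id", "time"], kind="stable").reset_index(drop=True)
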