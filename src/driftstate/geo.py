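"""Great-circle geometry on the WGS84 mean sphere.

All public functions accept scalars or numpy arrays of latitudes/longitudes in
decimal degrees (lat in [-90, 90], lon in (-180, 180]) and are vectorized.
"""

from __future__ import annotations

import numpy as np

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance between two points, in kilometres.

    Symmetric, non-negative, and exactly zero for coincident points.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for near-antipodal points
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lat1, lon1, lat2, lon2):
    """Forward azimuth from the first point to the second.

    Degrees clockwise from north, in (-180, 180]. Undefined (NaN) for
    coincident points.
    """
    la1, lo1, la2, lo2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lo2 - lo1
    y = np.sin(dlon) * np.cos(la2)
    x = np.cos(la1) * np.sin(la2) - np.sin(la1) * np.cos(la2) * np.cos(dlon)
    brg = np.degrees(np.arctan2(y, x))
    coincident = (np.asarray(lat1) == np.asarray(lat2)) & (np.asarray(lon1) == np.asarray(lon2))
    brg = np.where(coincident, np.nan, brg)
    # arctan2 returns [-180, 180]; map -180 -> 180 for the (-180, 180] convention
    brg = np.where(brg == -180.0, 180.0, brg)
    if np.isscalar(lat1) or np.ndim(brg) == 0:
        return float(brg)
    return brg


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along ``bearing_deg``.

    Spherical direct geodesic problem; returns (lat, lon) in degrees with
    longitude normalized to (-180, 180].
    """
    la1 = np.radians(np.asarray(lat, dtype=float))
    lo1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    la2 = np.arcsin(np.sin(la1) * np.cos(delta) + np.cos(la1) * np.sin(delta) * np.cos(brg))
    lo2 = lo1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(la1),
        np.cos(delta) - np.sin(la1) * np.sin(la2),
    )
    lat2 = np.degrees(la2)
    lon2 = normalize_lon(np.degrees(lo2))
    if np.ndim(lat2) == 0:
        return float(lat2), float(lon2)
    return lat2, lon2


def normalize_lon(lon):
    """Wrap longitudes into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    out = np.where(out == -180.0, 180.0, out)
    if np.ndim(out) == 0:
        return float(out)
    return out


def _to_unit_vectors(lat, lon):
    la = np.radians(np.asarray(lat, dtype=float))
    lo = np.radians(np.asarray(lon, dtype=float))
    return np.stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1)


def geographic_midpoint(lats, lons):
    """Geographic midpoint of points on the sphere.

    Normalized 3-D Cartesian mean of the unit vectors, re-projected to
    lat/lon; antimeridian-safe (unlike an arithmetic lat/lon mean).
    """
    v = _to_unit_vectors(lats, lons).mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0.0:  # antipodal degenerate cluster; fall back to first point
        return float(np.asarray(lats)[0]), float(np.asarray(lons)[0])
    v = v / norm
    lat = np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[1], v[0]))
    return float(lat), float(normalize_lon(lon))


def distance_to_polyline_km(lats, lons, line):
    """Minimum great-circle distance from each point to a lat/lon polyline.

    ``line`` is an (n, 2) array of (lat, lon) vertices. Uses the cross-track /
    along-track construction per segment, clamped to segment endpoints.
    """
    pts = np.atleast_2d(np.column_stack([np.atleast_1d(lats), np.atleast_1d(lons)])).astype(float)
    line = np.asarray(line, dtype=float)
    if line.shape[0] == 1:
        d = haversine_km(pts[:, 0], pts[:, 1], line[0, 0], line[0, 1])
        return d if d.ndim else float(d)

    a = line[:-1]  # segment starts, (m, 2)
    b = line[1:]   # segment ends
    # distances point -> segment start / end, (n, m)
    d_pa = haversine_km(pts[:, [0]], pts[:, [1]], a[None, :, 0], a[None, :, 1])
    d_pb = haversine_km(pts[:, [0]], pts[:, [1]], b[None, :, 0], b[None, :, 1])
    seg_len = haversine_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])[None, :]

    theta_ab = np.radians(initial_bearing(a[None, :, 0], a[None, :, 1], b[None, :, 0], b[None, :, 1]))
    theta_ap = np.radians(initial_bearing(a[None, :, 0], a[None, :, 1], pts[:, [0]], pts[:, [1]]))
    delta_ap = d_pa / EARTH_RADIUS_KM
    with np.errstate(invalid="ignore"):
        xt = np.arcsin(np.clip(np.sin(delta_ap) * np.sin(theta_ap - theta_ab), -1.0, 1.0))
        at = np.arccos(np.clip(np.cos(delta_ap) / np.maximum(np.cos(xt), 1e-12), -1.0, 1.0))
    cross_track = np.abs(xt) * EARTH_RADIUS_KM
    along_track = at * EARTH_RADIUS_KM
    # coincident with segment start -> bearing NaN -> distance 0
    cross_track = np.where(np.isnan(cross_track), 0.0, cross_track)
    along_track = np.where(np.isnan(along_track), 0.0, along_track)

    inside = (along_track >= 0.0) & (along_track <= seg_len)
    d_seg = np.where(inside, cross_track, np.minimum(d_pa, d_pb))
    out = d_seg.min(axis=1)
    if np.ndim(lats) == 0:
        return float(out[0])
    return out
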