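"""Cleaning of raw GPS buoy position streams.

Three steps, in order: drop rows without a valid latitude/longitude, collapse
same-hour fixes of a buoy to their geographic midpoint (several vessels can
monitor one buoy in the same hour, and sub-hour emissions share a timestamp
because minutes are not recorded), and remove "doubled" positions — a pair of
identical consecutive coordinates at different times produced by GPS capture
failures, which otherwise yield absurd implied speeds. Only the first fix of
an identical run is kept.

The beaching detector runs on the stream *before* doubled-position removal
(repeated identical fixes are its signal), so the chain can tag repeats
instead of discarding them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geo import geographic_midpoint


def drop_invalid(positions: pd.DataFrame) -> pd.DataFrame:
    """Remove rows with missing or out-of-range latitude/longitude."""
    lat = pd.to_numeric(positions["lat"], errors="coerce")
    lon = pd.to_numeric(positions["lon"], errors="coerce")
    ok = (
        lat.notna() & lon.notna()
        & lat.between(-90.0, 90.0)
        & (lon > -180.0) & (lon <= 180.0)
        & positions["time"].notna()
    )
    return positions.loc[ok].copy()


def collapse_hourly_duplicates(positions: pd.DataFrame) -> pd.DataFrame:
    """One position per (buoy, hour): the geographic midpoint of the fixes.

    The midpoint is the normalized 3-D Cartesian mean on the sphere
    (antimeridian-safe); SST is averaged over the available values.
    """
    df = positions.copy()
    df["time"] = df["time"].dt.floor("h")
    df = df.sort_values(["buoy_id", "time"], kind="stable")

    sizes = df.groupby(["buoy_id", "time"], sort=False)["lat"].transform("size")
    singles = df.loc[sizes == 1]
    multi = df.loc[sizes > 1]
    if multi.empty:
        return df.reset_index(drop=True)

    def _agg(g: pd.DataFrame) -> pd.Series:
        lat, lon = geographic_midpoint(g["lat"].to_numpy(), g["lon"].to_numpy())
        first = g.iloc[0].copy()
        first["lat"], first["lon"] = lat, lon
        if "sst" in g:
            first["sst"] = g["sst"].mean()
        return first

    collapsed = pd.DataFrame(
        [_agg(g) for _, g in multi.groupby(["buoy_id", "time"], sort=False)]
    )
    out = pd.concat([singles, collapsed], ignore_index=True)
    return out.sort_values(["buoy_id", "time"], kind="stable").reset_index(drop=True)


def remove_doubled_positions(track: pd.DataFrame, mode: str = "drop") -> pd.DataFrame:
    """Keep only the first of consecutive identical positions of each buoy.

    The rule is applied left to right, so a triple repeat keeps just its first
    fix. With ``mode="tag"`` the repeats are flagged in a boolean ``doubled``
    column instead of dropped (the form consumed by the beaching detector).
    """
    if mode not in ("drop", "tag"):
        raise ValueError("mode must be 'drop' or 'tag'")
    df = track.sort_values(["buoy_id", "time"], kind="stable").reset_index(drop=True)
    same_buoy = df["buoy_id"].eq(df["buoy_id"].shift())
    same_pos = df["lat"].eq(df["lat"].shift()) & df["lon"].eq(df["lon"].shift())
    repeat = (same_buoy & same_pos).to_numpy()
    if mode == "tag":
        df["doubled"] = repeat
        return df
    return df.loc[~repeat].reset_index(drop=True)


def clean(positions: pd.DataFrame, keep_repeats: bool = False) -> pd.DataFrame:
    """Full cleaning chain: invalid rows, hourly midpoints, doubled fixes.

    With ``keep_repeats=True`` doubled positions are tagged rather than
    removed, preserving the repeat runs the beaching detector relies on.
    The chain is idempotent.
    """
    df = drop_invalid(positions)
    df = collapse_hourly_duplicates(df)
    df = remove_doubled_positions(df, mode="tag" if keep_repeats else "drop")
    return df
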