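"""Per-dive metrics from compressed 6-point profiles.

Each transmitted dive is a 6-point time-depth profile: two surface points
(start, end) and four at-depth inflection points.  Transit rates are the
depth/time ratios of the first and last legs; the mean transit depth — the
mean of the depth where the descent ended and the ascent began — drives the
0-100 m weighting used by the foraging indexes.  Dive positions come from
linear interpolation along the smoothed track at the dive start time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import geo

logger = logging.getLogger(__name__)

T_COLS = [f"t_{i}" for i in range(6)]
D_COLS = [f"d_{i}" for i in range(6)]


def compute_transit_rates(dives: pd.DataFrame,
                          min_depth_m: float = 10.0) -> pd.DataFrame:
    """Descent/ascent rates (m/s, both positive) and mean transit depth.

    descent = (d1-d0)/(t1-t0); ascent = (d5-d4)/(t5-t4) sign-flipped so
    positive means upward travel; mean_transit_depth = (d1+d4)/2.  Dives
    with a zero-duration leg, an inverted leg, or max depth below
    ``min_depth_m`` are excluded (logged).
    """
    t = dives[T_COLS].to_numpy(float)
    d = dives[D_COLS].to_numpy(float)
    dt_desc = t[:, 1] - t[:, 0]
    dt_asc = t[:, 5] - t[:, 4]
    ok = (dt_desc > 0) & (dt_asc > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        descent = (d[:, 1] - d[:, 0]) / np.where(dt_desc > 0, dt_desc, np.nan)
        ascent = -(d[:, 5] - d[:, 4]) / np.where(dt_asc > 0, dt_asc, np.nan)
    ok &= (descent > 0) & (ascent > 0)
    ok &= dives.max_depth_m.to_numpy(float) >= min_depth_m
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("excluded %d dives (degenerate legs or < %g m)",
                    n_bad, min_depth_m)
    out = dives.loc[ok, ["dive_id", "animal_id", "start_time"]].copy()
    out["descent_rate"] = descent[ok]
    out["ascent_rate"] = ascent[ok]
    out["mean_transit_depth"] = (d[ok, 1] + d[ok, 4]) / 2.0
    return out.reset_index(drop=True)


def geolocate_dives(dives: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Attach lon/lat to each dive by linear interpolation along the track.

    The anchor instant is the dive *start* time.  Dives outside the track's
    time span are dropped with a warning.
    """
    if track.empty:
        raise ValueError("empty track")
    out = []
    for animal, dv in dives.groupby("animal_id", sort=False):
        tr = track[track.animal_id == animal].sort_values("time")
        if tr.empty:
            logger.warning("animal %s has no track; %d dives dropped",
                           animal, len(dv))
            continue
        tt = tr.time.values.astype("datetime64[ns]").astype("int64") / 1e9
        dt = dv.start_time.values.astype("datetime64[ns]").astype("int64") / 1e9
        in_span = (dt >= tt[0]) & (dt <= tt[-1])
        if (~in_span).any():
            logger.warning("animal %s: %d dives outside track span dropped",
                           animal, int((~in_span).sum()))
        dv = dv.loc[in_span].copy()
        dt = dt[in_span]
        idx = np.clip(np.searchsorted(tt, dt, side="right"), 1, len(tt) - 1)
        frac = (dt - tt[idx - 1]) / np.maximum(tt[idx] - tt[idx - 1], 1e-9)
        lon0 = tr.lon.to_numpy()[idx - 1]
        lat0 = tr.lat.to_numpy()[idx - 1]
        lon1 = tr.lon.to_numpy()[idx]
        lat1 = tr.lat.to_numpy()[idx]
        lons = np.empty(len(dv))
        lats = np.empty(len(dv))
        for i in range(len(dv)):
            lons[i], lats[i] = geo.intermediate_point(
                lon0[i], lat0[i], lon1[i], lat1[i], frac[i])
        dv["lon"] = lons
        dv["lat"] = lats
        out.append(dv)
    if not out:
        return dives.iloc[0:0].assign(lon=[], lat=[])
    return pd.concat(out, ignore_index=True)


def attach_context(dives: pd.DataFrame, track_points: pd.DataFrame) -> pd.DataFrame:
    """Carry season and trip labels from the nearest-in-time track point."""
    out = []
    for animal, dv in dives.groupby("animal_id", sort=False):
        tr = track_points[track_points.animal_id == animal].sort_values("time")
        if tr.empty:
            continue
        tt = tr.time.values.astype("datetime64[ns]").astype("int64")
        dt = dv.start_time.values.astype("datetime64[ns]").astype("int64")
        idx = np.clip(np.searchsorted(tt, dt), 0, len(tt) - 1)
        left = np.clip(idx - 1, 0, len(tt) - 1)
        nearer_left = np.abs(tt[left] - dt) < np.abs(tt[idx] - dt)
        idx = np.where(nearer_left, left, idx)
        dv = dv.copy()
        dv["season"] = tr.season.to_numpy()[idx] if "season" in tr else None
        dv["trip_id"] = tr.trip_id.to_numpy()[idx] if "trip_id" in tr else None
        out.append(dv)
    return pd.concat(out, ignore_index=True)


def daily_mean_max_depth(dives: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of max depth per UTC animal-day with >= 1 dive."""
    df = dives.copy()
    df["day"] = df.start_time.dt.floor("D")
    return (df.groupby(["animal_id", "day"], as_index=False)
              .agg(mean_max_depth=("max_depth_m", "mean"),
                   n_dives=("max_depth_m", "size")))
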