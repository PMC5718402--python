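"""First passage time (FPT) and area-restricted-search scale selection.

FPT at a track point is the time the animal takes to cross a circle of
radius r centred on that point — the interval from the last entry into the
circle (searching backward along the track) to the first exit (forward).
Slow, tortuous movement inflates FPT, so peaks flag area-restricted search
(ARS).  The ARS spatial scale is the radius maximizing the variance of FPT
across track points; tracks are first resampled to equidistant points along
the path so that slow sections are not oversampled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import geo

logger = logging.getLogger(__name__)


def resample_track_equidistant(points: pd.DataFrame,
                               spacing_km: float = 5.0) -> pd.DataFrame:
    """Interpolate a trip to points every ``spacing_km`` along the path.

    Positions are interpolated along each great-circle segment at cumulative
    path-distance multiples of the spacing; timestamps are interpolated
    proportionally within segments.  A trip shorter than the spacing yields
    its first point only.
    """
    if len(points) < 2:
        raise ValueError("need >= 2 points to resample")
    pts = points.sort_values("time")
    lon = pts.lon.to_numpy()
    lat = pts.lat.to_numpy()
    t_s = pts.time.values.astype("datetime64[ns]").astype("int64") / 1e9
    seg = geo.haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total < spacing_km:
        logger.warning("trip path (%.1f km) shorter than spacing; single point",
                       total)
        return pts.iloc[[0]][["animal_id", "time", "lon", "lat"]].assign(
            path_km=0.0).reset_index(drop=True)
    targets = np.arange(0.0, total + 1e-9, spacing_km)
    idx = np.clip(np.searchsorted(cum, targets, side="right"), 1, len(cum) - 1)
    frac = (targets - cum[idx - 1]) / np.maximum(seg[idx - 1], 1e-12)
    frac = np.clip(frac, 0.0, 1.0)
    out_lon = np.empty(len(targets))
    out_lat = np.empty(len(targets))
    for i, (j, f) in enumerate(zip(idx, frac)):
        out_lon[i], out_lat[i] = geo.intermediate_point(
            lon[j - 1], lat[j - 1], lon[j], lat[j], f)
    out_t = t_s[idx - 1] + frac * (t_s[idx] - t_s[idx - 1])
    return pd.DataFrame({
        "animal_id": pts.animal_id.iloc[0],
        "time": pd.to_datetime((out_t * 1e9).astype("int64")),
        "lon": out_lon, "lat": out_lat, "path_km": targets})


def fpt_at_radius(points: pd.DataFrame, r_km: float,
                  dist_matrix: np.ndarray | None = None) -> np.ndarray:
    """FPT (hours) at every point for one radius; NaN where undefined.

    Crossing instants are linearly interpolated in distance-to-centre on the
    segment that crosses the circle.  Points whose circle is never exited
    forward (or never entered backward) within the track get NaN.
    """
    if r_km <= 0:
        raise ValueError("radius must be positive")
    lon = points.lon.to_numpy()
    lat = points.lat.to_numpy()
    t_hr = points.time.values.astype("datetime64[ns]").astype("int64") / 1e9 / 3600.0
    n = len(points)
    if dist_matrix is None:
        dist_matrix = pairwise_distances(points)
    fpt = np.full(n, np.nan)
    for i in range(n):
        d = dist_matrix[i]
        out = d > r_km
        # forward exit
        fwd = np.where(out[i:])[0]
        if len(fwd) == 0:
            continue
        j = i + fwd[0]            # first point outside, j > i
        f = (r_km - d[j - 1]) / max(d[j] - d[j - 1], 1e-12)
        t_exit = t_hr[j - 1] + f * (t_hr[j] - t_hr[j - 1])
        # backward entry
        back = np.where(out[:i + 1][::-1])[0]
        if len(back) == 0:
            continue
        k = i - back[0]           # last point outside before i, k < i
        # moving from outside (k) to inside (k+1): interpolate on that segment
        f_in = (d[k] - r_km) / max(d[k] - d[k + 1], 1e-12)
        t_entry = t_hr[k] + f_in * (t_hr[k + 1] - t_hr[k])
        fpt[i] = t_exit - t_entry
    return fpt


def pairwise_distances(points: pd.DataFrame) -> np.ndarray:
    lon = points.lon.to_numpy()
    lat = points.lat.to_numpy()
    return geo.haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def fpt_profile(points: pd.DataFrame, radii_km) -> pd.DataFrame:
    """FPT at every point for each radius (long format)."""
    dm = pairwise_distances(points)
    frames = []
    for r in radii_km:
        vals = fpt_at_radius(points, r, dm)
        frames.append(pd.DataFrame({
            "animal_id": points.animal_id.to_numpy(),
            "time": points.time.to_numpy(),
            "lon": points.lon.to_numpy(), "lat": points.lat.to_numpy(),
            "radius_km": float(r), "fpt_hr": vals}))
    return pd.concat(frames, ignore_index=True)


def select_ars_scale(trips: list[pd.DataFrame],
                     radii_km=np.arange(5.0, 101.0, 1.0),
                     basis: str = "log"):
    """ARS scale = radius maximizing the variance of FPT over all points.

    ``trips`` is a list of equidistantly resampled trips.  Variance is taken
    on log FPT by default — on tracks mixing transit with patch dwell the
    raw-FPT variance grows monotonically with radius (ever more points see
    the dwell), so it cannot peak at the search scale; the log transform is
    also the originating method's standard.  ``basis="raw"`` remains
    available.  Returns
    ``(selected_radius_km, curve)`` where curve has columns radius_km,
    var_fpt, var_log_fpt, n.  Radii where all FPT are missing are skipped;
    a flat curve (straight-line track) is flagged non-informative.
    """
    if not trips:
        raise ValueError("need at least one trip")
    mats = [pairwise_distances(tp) for tp in trips]
    rows = []
    for r in radii_km:
        vals = np.concatenate([fpt_at_radius(tp, r, dm)
                               for tp, dm in zip(trips, mats)])
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            logger.info("radius %.0f km: all FPT missing; skipped", r)
            continue
        rows.append((float(r), float(np.var(vals, ddof=1)),
                     float(np.var(np.log(vals[vals > 0]), ddof=1)),
                     len(vals)))
    curve = pd.DataFrame(rows, columns=["radius_km", "var_fpt",
                                        "var_log_fpt", "n"])
    if curve.empty:
        raise ValueError("no radius produced any finite FPT")
    col = "var_fpt" if basis == "raw" else "var_log_fpt"
    informative = curve[col].max() > 1.05 * max(curve[col].min(), 1e-12)
    if not informative:
        logger.warning("FPT variance curve is flat; scale non-informative")
    selected = float(curve.radius_km.iloc[int(np.argmax(curve[col].to_numpy()))])
    return selected, curve


def exclude_haulout_fpt(fpt_points: pd.DataFrame, haulouts: pd.DataFrame,
                        haulout_positions: pd.DataFrame,
                        scale_km: float) -> pd.DataFrame:
    """Drop FPT points within ``scale_km`` of any haul-out position.

    ``haulout_positions`` carries one (lon, lat) row per haul-out site.
    """
    if haulout_positions is None or haulout_positions.empty:
        return fpt_points
    keep = np.ones(len(fpt_points), dtype=bool)
    lon = fpt_points.lon.to_numpy()
    lat = fpt_points.lat.to_numpy()
    for r in haulout_positions.itertuples():
        keep &= geo.haversine_km(lon, lat, r.lon, r.lat) > scale_km
    return fpt_points.loc[keep].reset_index(drop=True)


def daily_fpt(fpt_points: pd.DataFrame) -> pd.DataFrame:
    """Mean FPT (hours) per UTC animal-day; days with no points are absent."""
    df = fpt_points.dropna(subset=["fpt_hr"]).copy()
    df["day"] = df.time.dt.floor("D")
    return (df.groupby(["animal_id", "day"], as_index=False)
              .agg(daily_fpt_hr=("fpt_hr", "mean"), n_points=("fpt_hr", "size")))


def foraging_days(daily: pd.DataFrame, q: float = 0.75,
                  scope: str = "pooled") -> pd.DataFrame:
    """Flag animal-days whose mean FPT strictly exceeds the q-quantile.

    The quantile (type 7, the numpy default) is computed over the pooled
    daily values by default, or per animal with ``scope="per_animal"``.
    """
    if len(daily) < 4:
        raise ValueError("need >= 4 daily values to set a quantile")
    out = daily.copy()
    if scope == "pooled":
        thr = float(np.quantile(out.daily_fpt_hr.to_numpy(), q))
        out["fpt_threshold_hr"] = thr
    elif scope == "per_animal":
        out["fpt_threshold_hr"] = out.groupby("animal_id").daily_fpt_hr \
            .transform(lambda v: float(np.quantile(v.to_numpy(), q)))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out["foraging"] = out.daily_fpt_hr > out.fpt_threshold_hr
    return out
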