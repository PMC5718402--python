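"""Argos track cleaning, state-space smoothing, and season/trip segmentation.

The cleaning stage is a speed-distance-angle (SDA) filter: location class Z
is dropped outright, fixes requiring implausible swimming speed to *both*
neighbours are removed (McConnell test), and near-collinear out-and-back
spikes are removed by angle/leg-length rules.  The cleaned fixes are then
smoothed with a continuous-time correlated random walk (CTCRW) state-space
model — integrated Ornstein-Uhlenbeck velocity — fitted by maximum
likelihood in a local tangent-plane projection, with per-location-class
measurement error and velocity pinned to zero during haul-out intervals.
Regularly spaced track points with a positional standard error come from the
Rauch-Tung-Striebel smoother.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import geo
from .config import DEFAULT_ARGOS_ERROR_SD_KM

logger = logging.getLogger(__name__)

DEFAULT_SPIKE_RULES = ((15.0, 2.5), (25.0, 5.0))  # (max angle deg, min leg km)


# ---------------------------------------------------------------------------
# SDA filter

def _speeds_ms(lon, lat, t_s):
    d_km = geo.haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt = np.diff(t_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt > 0, d_km * 1000.0 / dt, np.inf)


def _internal_angles(lon, lat):
    """Interior angle (deg) at each fix between the legs to its neighbours."""
    b_back = geo.initial_bearing_deg(lon[1:-1], lat[1:-1], lon[:-2], lat[:-2])
    b_fwd = geo.initial_bearing_deg(lon[1:-1], lat[1:-1], lon[2:], lat[2:])
    ang = np.abs((b_back - b_fwd + 180.0) % 360.0 - 180.0)
    return ang


def _sda_one(df: pd.DataFrame, vmax_ms: float, spike_rules) -> pd.DataFrame:
    df = df[df.lc != "Z"]
    if len(df) < 3:
        return df
    keep = df.copy()
    changed = True
    while changed and len(keep) >= 3:
        changed = False
        lon = keep.lon.to_numpy()
        lat = keep.lat.to_numpy()
        t_s = keep.time.values.astype("datetime64[ns]").astype("int64") / 1e9
        sp = _speeds_ms(lon, lat, t_s)
        both = np.maximum(sp[:-1], 0) > vmax_ms
        both = both & (sp[1:] > vmax_ms)          # interior fix i+1 uses sp[i], sp[i+1]
        if both.any():
            # remove the single worst violator, then re-evaluate
            idx = np.where(both)[0]
            worst = idx[np.argmax(np.minimum(sp[idx], sp[idx + 1]))] + 1
            keep = keep.drop(keep.index[worst])
            changed = True
            continue
        ang = _internal_angles(lon, lat)
        leg_back = geo.haversine_km(lon[1:-1], lat[1:-1], lon[:-2], lat[:-2])
        leg_fwd = geo.haversine_km(lon[1:-1], lat[1:-1], lon[2:], lat[2:])
        spike = np.zeros(len(ang), dtype=bool)
        for theta, leg_km in spike_rules:
            spike |= (ang < theta) & (leg_back > leg_km) & (leg_fwd > leg_km)
        if spike.any():
            worst = int(np.where(spike)[0][np.argmin(ang[spike])]) + 1
            keep = keep.drop(keep.index[worst])
            changed = True
    return keep


def sda_filter(fixes: pd.DataFrame, vmax_ms: float = 2.0,
               spike_rules=DEFAULT_SPIKE_RULES) -> pd.DataFrame:
    """Speed-distance-angle filter on raw Argos fixes.

    Removes all LC-Z fixes, fixes whose travel to both neighbours would
    require speed above ``vmax_ms``, and spikes whose interior angle is
    below a rule's angle with both legs longer than the rule's length.
    Idempotent: the filter iterates to a fixed point.
    """
    out = []
    for animal, df in fixes.sort_values(["animal_id", "time"]).groupby(
            "animal_id", sort=False):
        df = df.drop_duplicates(subset="time")
        if len(df) < 3:
            logger.warning("animal %s has <3 fixes; returned unchanged", animal)
            out.append(df)
            continue
        out.append(_sda_one(df, vmax_ms, spike_rules))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# CTCRW state-space smoother

@dataclass
class CtcrwParams:
    beta: float    # 1/hr, velocity autocorrelation decay
    sigma: float   # km/hr^(3/2), velocity diffusion


def _ctcrw_mats(dt_hr: float, beta: float, sigma: float):
    """Transition F and process covariance Q for one axis of the CTCRW."""
    phi = math.exp(-beta * dt_hr)
    F = ((1.0, (1.0 - phi) / beta), (0.0, phi))
    s2 = sigma * sigma
    qvv = s2 / (2 * beta) * (1 - phi * phi)
    qxv = s2 / (2 * beta * beta) * (1 - phi) ** 2
    qxx = s2 / (beta * beta) * (dt_hr - 2 * (1 - phi) / beta
                                + (1 - phi * phi) / (2 * beta))
    return F, (qxx, qxv, qvv)

_STILL_F = ((1.0, 0.0), (0.0, 0.0))
_STILL_Q = (1e-8, 0.0, 1e-8)


def _run_kalman(t_hr, x_obs, y_obs, obs_sd, is_obs, still, beta, sigma,
                smooth: bool):
    """Shared-covariance 2x(2-state) Kalman filter (+RTS smoother).

    Because both axes share F, Q and R, a single covariance recursion serves
    both; only the means differ.  Returns (loglik, xs, ys, se) where se is
    the per-time positional standard error (post-smoothing if smooth).
    """
    n = len(t_hr)
    mx = [0.0, 0.0]
    my = [0.0, 0.0]
    # diffuse-ish init at first observation
    first = int(np.argmax(is_obs))
    mx[0], my[0] = x_obs[first], y_obs[first]
    P = [[obs_sd[first] ** 2 + 25.0, 0.0], [0.0, 25.0]]
    ll = 0.0
    Fs, Pp, Pf, mxs, mys, mpx, mpy = [], [], [], [], [], [], []
    for i in range(n):
        if i > 0:
            dt = t_hr[i] - t_hr[i - 1]
            if still[i]:
                F, (qxx, qxv, qvv) = _STILL_F, _STILL_Q
            else:
                F, (qxx, qxv, qvv) = _ctcrw_mats(max(dt, 1e-6), beta, sigma)
            a, b = F[0]
            c, d = F[1]
            nmx = [a * mx[0] + b * mx[1], c * mx[0] + d * mx[1]]
            nmy = [a * my[0] + b * my[1], c * my[0] + d * my[1]]
            p00, p01, p11 = P[0][0], P[0][1], P[1][1]
            fp00 = a * p00 + b * p01
            fp01 = a * p01 + b * p11
            gp00 = c * p00 + d * p01
            gp01 = c * p01 + d * p11
            P = [[fp00 * a + fp01 * b + qxx, fp00 * c + fp01 * d + qxv],
                 [gp00 * a + gp01 * b + qxv, gp00 * c + gp01 * d + qvv]]
            mx, my = nmx, nmy
        else:
            F = ((1.0, 0.0), (0.0, 1.0))
        Fs.append(F)
        mpx.append(list(mx))
        mpy.append(list(my))
        Pp.append([list(P[0]), list(P[1])])
        if is_obs[i]:
            r = obs_sd[i] ** 2
            S = P[0][0] + r
            k0 = P[0][0] / S
            k1 = P[1][0] / S
            vx = x_obs[i] - mx[0]
            vy = y_obs[i] - my[0]
            ll += -0.5 * (2 * math.log(2 * math.pi * S) + (vx * vx + vy * vy) / S)
            mx = [mx[0] + k0 * vx, mx[1] + k1 * vx]
            my = [my[0] + k0 * vy, my[1] + k1 * vy]
            p00, p01, p11 = P[0][0], P[0][1], P[1][1]
            P = [[(1 - k0) * p00, (1 - k0) * p01],
                 [p01 - k1 * p00, p11 - k1 * p01]]
        mxs.append(list(mx))
        mys.append(list(my))
        Pf.append([list(P[0]), list(P[1])])
    if not smooth:
        return ll, None, None, None
    # RTS smoother
    sx = [None] * n
    sy = [None] * n
    sP = [None] * n
    sx[-1], sy[-1], sP[-1] = mxs[-1], mys[-1], Pf[-1]
    for i in range(n - 2, -1, -1):
        F = Fs[i + 1]
        a, b = F[0]
        c, d = F[1]
        Pfi = Pf[i]
        Ppn = Pp[i + 1]
        # C = Pf F' Ppn^{-1}
        pf00, pf01, pf11 = Pfi[0][0], Pfi[0][1], Pfi[1][1]
        pfF00 = pf00 * a + pf01 * b
        pfF01 = pf00 * c + pf01 * d
        pfF10 = pf01 * a + pf11 * b
        pfF11 = pf01 * c + pf11 * d
        det = Ppn[0][0] * Ppn[1][1] - Ppn[0][1] * Ppn[1][0]
        det = det if abs(det) > 1e-300 else 1e-300
        i00, i01 = Ppn[1][1] / det, -Ppn[0][1] / det
        i10, i11 = -Ppn[1][0] / det, Ppn[0][0] / det
        C00 = pfF00 * i00 + pfF01 * i10
        C01 = pfF00 * i01 + pfF01 * i11
        C10 = pfF10 * i00 + pfF11 * i10
        C11 = pfF10 * i01 + pfF11 * i11
        dx0 = sx[i + 1][0] - mpx[i + 1][0]
        dx1 = sx[i + 1][1] - mpx[i + 1][1]
        dy0 = sy[i + 1][0] - mpy[i + 1][0]
        dy1 = sy[i + 1][1] - mpy[i + 1][1]
        sx[i] = [mxs[i][0] + C00 * dx0 + C01 * dx1,
                 mxs[i][1] + C10 * dx0 + C11 * dx1]
        sy[i] = [mys[i][0] + C00 * dy0 + C01 * dy1,
                 mys[i][1] + C10 * dy0 + C11 * dy1]
        dP00 = sP[i + 1][0][0] - Ppn[0][0]
        dP01 = sP[i + 1][0][1] - Ppn[0][1]
        dP10 = sP[i + 1][1][0] - Ppn[1][0]
        dP11 = sP[i + 1][1][1] - Ppn[1][1]
        t00 = C00 * dP00 + C01 * dP10
        t01 = C00 * dP01 + C01 * dP11
        t10 = C10 * dP00 + C11 * dP10
        t11 = C10 * dP01 + C11 * dP11
        sP[i] = [[Pfi[0][0] + t00 * C00 + t01 * C01,
                  Pfi[0][1] + t00 * C10 + t01 * C11],
                 [Pfi[1][0] + t10 * C00 + t11 * C01,
                  Pfi[1][1] + t10 * C10 + t11 * C11]]
    xs = np.array([s[0] for s in sx])
    ys = np.array([s[0] for s in sy])
    se = np.sqrt(np.maximum([p[0][0] for p in sP], 0.0))
    return ll, xs, ys, se


def _in_any_interval(times, intervals) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for s, e in intervals:
        mask |= (times >= s) & (times <= e)
    return mask


def smooth_track(fixes: pd.DataFrame, haulouts: pd.DataFrame | None = None,
                 interval_hr: float = 1.0,
                 error_sd_by_lc: dict | None = None,
                 max_gap_hr: float = 72.0,
                 estimate: bool = True) -> pd.DataFrame:
    """CTCRW smoothing of SDA-filtered fixes to a regular track.

    Returns TrackPoints (animal_id, time, lon, lat, position_se km,
    hauled_out) at multiples of ``interval_hr``.  Velocity is forced to zero
    within haul-out intervals.  Gaps longer than ``max_gap_hr`` split the
    track into independently smoothed segments.
    """
    if fixes.empty:
        raise ValueError("no fixes to smooth")
    sd_map = dict(DEFAULT_ARGOS_ERROR_SD_KM if error_sd_by_lc is None
                  else error_sd_by_lc)
    worst = max(sd_map.values())
    sd_map.setdefault("A", worst)
    sd_map.setdefault("B", worst)
    out = []
    for animal, df in fixes.sort_values(["animal_id", "time"]).groupby(
            "animal_id", sort=False):
        df = df.drop_duplicates(subset="time")
        ho = [] if haulouts is None else [
            (r.start, r.end) for r in
            haulouts[haulouts.animal_id == animal].itertuples()]
        gaps = df.time.diff().dt.total_seconds().to_numpy() / 3600.0
        seg_id = np.concatenate([[0], np.cumsum(gaps[1:] > max_gap_hr)])
        if seg_id.max() > 0:
            logger.warning("animal %s: %d gap(s) > %.0f hr; track split",
                           animal, int(seg_id.max()), max_gap_hr)
        for _s, seg in df.groupby(seg_id):
            if len(seg) < 3:
                continue
            out.append(_smooth_segment(animal, seg, ho, interval_hr, sd_map,
                                       estimate))
    return pd.concat(out, ignore_index=True)


def _smooth_segment(animal, seg, haulout_ivals, interval_hr, sd_map, estimate):
    proj = geo.LocalProjection(float(seg.lon.mean()), float(seg.lat.mean()))
    xo, yo = proj.forward(seg.lon.to_numpy(), seg.lat.to_numpy())
    t0 = seg.time.iloc[0]
    t_obs = (seg.time - t0).dt.total_seconds().to_numpy() / 3600.0
    sd_obs = np.array([max(sd_map.get(c, max(sd_map.values())), 0.05)
                       for c in seg.lc])
    t_end = t_obs[-1]
    t_grid = np.arange(0.0, t_end + 1e-9, interval_hr)
    t_all = np.concatenate([t_obs, t_grid])
    x_all = np.concatenate([xo, np.zeros(len(t_grid))])
    y_all = np.concatenate([yo, np.zeros(len(t_grid))])
    sd_all = np.concatenate([sd_obs, np.ones(len(t_grid))])
    is_obs = np.concatenate([np.ones(len(t_obs), bool), np.zeros(len(t_grid), bool)])
    order = np.argsort(t_all, kind="stable")
    t_all, x_all, y_all, sd_all, is_obs = (a[order] for a in
                                           (t_all, x_all, y_all, sd_all, is_obs))
    times_abs = t0 + pd.to_timedelta(t_all, unit="h")
    still = _in_any_interval(times_abs, haulout_ivals)

    def nll(theta):
        beta, sigma = math.exp(theta[0]), math.exp(theta[1])
        ll, *_ = _run_kalman(t_all, x_all, y_all, sd_all, is_obs, still,
                             beta, sigma, smooth=False)
        return -ll

    beta, sigma = 0.3, 3.0
    if estimate:
        res = minimize(nll, [math.log(beta), math.log(sigma)],
                       method="Nelder-Mead",
                       options={"maxiter": 60, "xatol": 0.05, "fatol": 0.5})
        beta, sigma = math.exp(res.x[0]), math.exp(res.x[1])
    _, xs, ys, se = _run_kalman(t_all, x_all, y_all, sd_all, is_obs, still,
                                beta, sigma, smooth=True)
    sel = ~is_obs
    lon, lat = proj.inverse(xs[sel], ys[sel])
    return pd.DataFrame({
        "animal_id": animal,
        "time": times_abs[sel],
        "lon": np.atleast_1d(lon), "lat": np.atleast_1d(lat),
        "position_se": se[sel],
        "hauled_out": still[sel],
    })


# ---------------------------------------------------------------------------
# seasons and trips

def segment_seasons(track: pd.DataFrame, animal_classes: dict,
                    haulouts: pd.DataFrame,
                    molt_onset: dict | None = None) -> pd.DataFrame:
    """Label each TrackPoint post_breeding or post_molting.

    Adults: post-breeding runs from the record start (tagging at breeding)
    to the molt onset (per-animal date, default July 1 of the deployment
    year).  Pups: the post-breeding season ends at the start of the first
    haul-out event after June 15; with no qualifying haul-out the boundary
    is the record end and the point set is flagged.
    """
    out = []
    for animal, df in track.groupby("animal_id", sort=False):
        df = df.sort_values("time").copy()
        cls = animal_classes.get(animal, "female")
        year = df.time.iloc[0].year
        flagged = False
        if cls == "pup":
            cutoff = pd.Timestamp(year=year, month=6, day=15)
            ho = haulouts[(haulouts.animal_id == animal)
                          & (haulouts.start > cutoff)]
            if len(ho):
                boundary = ho.start.min()
            else:
                # no qualifying haul-out: boundary at record end (inclusive)
                boundary = df.time.iloc[-1] + pd.Timedelta(nanoseconds=1)
                flagged = True
        else:
            if molt_onset and animal in molt_onset:
                boundary = pd.Timestamp(molt_onset[animal])
            else:
                boundary = pd.Timestamp(year=year, month=7, day=1)
        df["season"] = np.where(df.time < boundary, "post_breeding",
                                "post_molting")
        df["season_flagged"] = flagged
        out.append(df)
    return pd.concat(out, ignore_index=True)


def segment_trips(track: pd.DataFrame, animal_classes: dict,
                  center=(13.50, 73.86),
                  threshold_km: float = 250.0):
    """Divide season-labelled tracks into trips.

    Adults: a trip starts at the last fix inside the ``threshold_km`` disc
    around the deployment centre before an excursion and ends at the first
    fix back inside (complete) or at the record end (incomplete).  Pups:
    trips are delimited by season boundaries regardless of the disc.
    Returns ``(points, trips)`` where points carry a trip_id column and
    trips is one row per trip.
    """
    pts_out, trips = [], []
    for animal, df in track.groupby("animal_id", sort=False):
        df = df.sort_values("time").copy()
        cls = animal_classes.get(animal, "female")
        df["trip_id"] = None
        n_trip = 0
        if cls == "pup":
            for season, sdf in df.groupby("season", sort=False):
                n_trip += 1
                tid = f"{animal}_t{n_trip}"
                df.loc[sdf.index, "trip_id"] = tid
                complete = sdf.time.iloc[-1] < df.time.iloc[-1]
                trips.append((tid, animal, cls, season, complete,
                              sdf.time.iloc[0], sdf.time.iloc[-1]))
        else:
            dist = geo.haversine_km(df.lon.to_numpy(), df.lat.to_numpy(),
                                    center[0], center[1])
            inside = dist <= threshold_km
            i = 0
            n = len(df)
            while i < n:
                if inside[i]:
                    i += 1
                    continue
                # run of outside points [i, j)
                j = i
                while j < n and not inside[j]:
                    j += 1
                start_idx = i - 1 if i > 0 else i
                end_idx = j if j < n else n - 1
                complete = j < n
                n_trip += 1
                tid = f"{animal}_t{n_trip}"
                sel = df.index[start_idx:end_idx + 1]
                df.loc[sel, "trip_id"] = df.loc[sel, "trip_id"].where(
                    df.loc[sel, "trip_id"].notna(), tid)
                sdf = df.loc[sel]
                season = sdf.season.mode().iloc[0] if "season" in sdf else None
                trips.append((tid, animal, cls, season, complete,
                              sdf.time.iloc[0], sdf.time.iloc[-1]))
                i = j
            if n_trip == 0:
                logger.warning("animal %s never left the %d km disc; 0 trips",
                               animal, threshold_km)
        pts_out.append(df)
    points = pd.concat(pts_out, ignore_index=True)
    trips_df = pd.DataFrame(trips, columns=[
        "trip_id", "animal_id", "class", "season", "complete",
        "start_time", "end_time"])
    return points, trips_df
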