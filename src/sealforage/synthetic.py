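"""Synthetic SRDL data generator with known ground truth.

Emulates the data stream of a CTD Satellite Relay Data Logger deployed on a
hooded seal: Argos fixes with location-class-dependent error, compressed
6-point dive profiles (4 at-depth inflection points plus the two surface
end points), 17-point CTD casts, and haul-out intervals.  The latent
movement model is a correlated random walk that alternates directed transit
with slow, tortuous area-restricted search (ARS) inside prey patches, with
haul-outs at the deployment site between trips.  ARS arises mechanistically
from the speed/turning switch so that first-passage-time detection of the
patches downstream is a genuine inference test, not a tautology.

Drift dives are injected with probability ``drift_dive_prob``; their passive
segment's vertical rate follows the configured body-condition trajectory
(m/s, negative = sinking) plus noise, so the drift-rate pipeline can be
validated against a known condition history.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import geo
from .config import ANIMAL_CLASSES, GroundTruth, SimConfig
from .envgrid import EnvGrid, save_grid

logger = logging.getLogger(__name__)

DEFAULT_START = pd.Timestamp("2008-03-20T00:00:00")

#: Nominal CTD sampling depths (m); 17 representative points per cast.
CTD_DEPTHS = np.array([6, 12, 20, 30, 45, 60, 80, 100, 130, 160,
                       200, 250, 300, 350, 400, 450, 500], dtype=float)

# class -> (median max depth m, lognormal sigma, median duration min, sigma)
DIVE_PARAMS = {
    "pup": (75.0, 0.55, 4.5, 0.45),
    "female": (230.0, 0.45, 12.0, 0.35),
    "male": (235.0, 0.50, 13.0, 0.40),
}
# class -> median post-dive surface time (s)
SURFACE_PARAMS = {"pup": 62.0, "female": 100.0, "male": 95.0}


@dataclass
class SrdlDataset:
    """Everything one simulation run produces."""

    fixes: pd.DataFrame
    dives: pd.DataFrame
    ctd: pd.DataFrame
    haulouts: pd.DataFrame
    truth: GroundTruth
    bathymetry: EnvGrid
    ice: EnvGrid
    sst: EnvGrid
    config: SimConfig


# ---------------------------------------------------------------------------
# rasters

def _bathy_values(lon, lat, patches):
    depth = np.full(np.broadcast(lon, lat).shape, 2600.0)
    for (plon, plat, r_km, _dwell) in patches:
        d = geo.haversine_km(lon, lat, plon, plat)
        depth = depth - 2200.0 * np.exp(-0.5 * (d / (1.8 * r_km)) ** 2)
    return np.clip(depth, 80.0, None)


def _sst_values(lon, lat, month):
    base = 11.5 - 0.5 * (lat - 60.0) + 1.5 * np.sin(2 * np.pi * (month - 4) / 12.0)
    base = base + 0.03 * (lon - 5.0)
    return np.clip(base, -1.9, None)


def _ice_values(lon, lat, month):
    seasonal = 0.5 + 0.5 * np.cos(2 * np.pi * (month - 3) / 12.0)
    frac = np.clip((lat - 74.0) / 6.0, 0.0, 1.0) * seasonal
    return np.clip(frac, 0.0, 1.0)


def make_rasters(config: SimConfig, start=DEFAULT_START):
    """Synthetic bathymetry / ice / SST grids covering the simulated region."""
    lon = np.arange(-20.0, 40.01, 0.25)
    lat = np.arange(58.0, 84.01, 0.125)
    LON, LAT = np.meshgrid(lon, lat)
    patches = [(c[0], c[1], config.patch_radius_km, config.patch_dwell_factor)
               for c in config.patch_centers]
    bathy = xr.DataArray(_bathy_values(LON, LAT, patches),
                         coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))
    times = pd.date_range(start - pd.Timedelta(days=30),
                          start + pd.Timedelta(days=config.duration_days + 30),
                          freq="MS")
    if len(times) < 2:
        times = pd.DatetimeIndex([start - pd.Timedelta(days=30),
                                  start + pd.Timedelta(days=30)])
    sst = xr.DataArray(
        np.stack([_sst_values(LON, LAT, t.month + t.day / 31.0) for t in times]),
        coords={"time": times, "lat": lat, "lon": lon}, dims=("time", "lat", "lon"))
    ice = xr.DataArray(
        np.stack([_ice_values(LON, LAT, t.month + t.day / 31.0) for t in times]),
        coords={"time": times, "lat": lat, "lon": lon}, dims=("time", "lat", "lon"))
    return (EnvGrid(bathy, "bathymetry_m"), EnvGrid(ice, "ice_fraction"),
            EnvGrid(sst, "sst_C"))


# ---------------------------------------------------------------------------
# latent movement

def _simulate_latent_one(animal_id, config: SimConfig, rng, start):
    """One animal's latent path at the fix interval: transit / ARS / haul-out."""
    dt_hr = config.fix_interval_hr
    n_steps = int(round(config.duration_days * 24.0 / dt_hr))
    speed_kmh = config.transit_speed_ms * 3.6
    step_sd = 0.1
    c_lon, c_lat = config.deployment_center
    lon = c_lon + rng.normal(0, 0.02)
    lat = c_lat + rng.normal(0, 0.01)
    dwell_hr = (config.patch_dwell_factor
                * 2.0 * config.patch_radius_km / speed_kmh)

    rows = []
    haulouts = []
    mode = "haulout"
    heading = float(rng.uniform(0, 360))
    patch_cycle = 0
    target = None            # (lon, lat) waypoint
    phase = "haulout"        # haulout -> outbound -> ars -> inbound
    phase_left_hr = config.haulout_days * 24.0
    haul_start = 0.0
    ars_left_hr = 0.0
    subtarget = None

    for i in range(n_steps + 1):
        t_hr = i * dt_hr
        rows.append((animal_id, t_hr, lon, lat, mode))
        if i == n_steps:
            break
        if phase == "haulout":
            phase_left_hr -= dt_hr
            if phase_left_hr <= 0:
                haulouts.append((haul_start, t_hr + dt_hr))
                if config.patch_centers:
                    target = tuple(config.patch_centers[
                        patch_cycle % len(config.patch_centers)])
                    patch_cycle += 1
                    phase, mode = "outbound", "transit"
                else:
                    phase, mode = "inbound", "transit"
                    target = (c_lon, c_lat)
            # stay put (tiny shuffle on the ice)
            continue
        speed = max(rng.normal(speed_kmh, step_sd * speed_kmh), 0.1)
        if phase in ("outbound", "inbound"):
            brg = geo.initial_bearing_deg(lon, lat, target[0], target[1])
            heading = brg + rng.normal(0, 15.0)
            step = speed * dt_hr
            lon, lat = geo.destination(lon, lat, heading, step)
            dist = geo.haversine_km(lon, lat, target[0], target[1])
            if phase == "outbound" and dist <= config.patch_radius_km * 0.5:
                phase, mode = "ars", "ars"
                ars_left_hr = dwell_hr * rng.uniform(0.7, 1.3)
            elif phase == "inbound" and dist <= 20.0:
                phase, mode = "haulout", "haulout"
                phase_left_hr = config.haulout_days * 24.0
                haul_start = t_hr + dt_hr
        elif phase == "ars":
            # slow, tortuous search that ranges over the whole patch: head
            # toward a random prey spot in the patch, re-drawn when reached
            if subtarget is None or geo.haversine_km(
                    lon, lat, subtarget[0], subtarget[1]) < 3.0:
                brg = rng.uniform(0, 360)
                rad = config.patch_radius_km * np.sqrt(rng.uniform())
                subtarget = geo.destination(target[0], target[1], brg, rad)
            brg = geo.initial_bearing_deg(lon, lat, subtarget[0], subtarget[1])
            heading = brg + rng.normal(0, 40.0)
            # slower than transit, but fast enough that the bout's path
            # (speed x dwell ~ 5 patch radii) actually covers the patch;
            # the time enrichment per unit area still scales as dwell_factor
            step = (speed * 2.5 / config.patch_dwell_factor) * dt_hr
            lon, lat = geo.destination(lon, lat, heading, step)
            ars_left_hr -= dt_hr
            if ars_left_hr <= 0:
                phase, mode = "inbound", "transit"
                target = (c_lon, c_lat)
                subtarget = None
    if phase == "haulout":
        haulouts.append((haul_start, n_steps * dt_hr))
    track = pd.DataFrame(rows, columns=["animal_id", "t_hr", "lon", "lat", "mode"])
    track["time"] = start + pd.to_timedelta(track.t_hr, unit="h")
    hdf = pd.DataFrame(haulouts, columns=["start_hr", "end_hr"])
    hdf["animal_id"] = animal_id
    hdf["start"] = start + pd.to_timedelta(hdf.start_hr, unit="h")
    hdf["end"] = start + pd.to_timedelta(hdf.end_hr, unit="h")
    return track, hdf[["animal_id", "start", "end"]]


def _observe_argos(latent: pd.DataFrame, config: SimConfig, rng) -> pd.DataFrame:
    """Add per-fix Argos error with a drawn location class; inject spikes."""
    lcs = list(config.lc_probs)
    probs = np.array([config.lc_probs[k] for k in lcs], dtype=float)
    probs = probs / probs.sum()
    fixes = []
    for animal, tr in latent.groupby("animal_id", sort=False):
        n = len(tr)
        lc = rng.choice(lcs, size=n, p=probs)
        sd = np.array([config.argos_error_sd_by_lc.get(c, 50.0) for c in lc])
        sd = np.where(np.asarray(lc) == "Z", 50.0, sd)
        proj = geo.LocalProjection(float(tr.lon.iloc[0]), float(tr.lat.iloc[0]))
        x, y = proj.forward(tr.lon.to_numpy(), tr.lat.to_numpy())
        x = x + rng.normal(0, 1, n) * sd
        y = y + rng.normal(0, 1, n) * sd
        artifact = np.zeros(n, dtype=bool)
        if config.n_spike_fixes > 0 and n > 4:
            # spikes are isolated single-fix displacements perpendicular to
            # the path, away from Z fixes: adjacent or along-track
            # displacements would be geometrically plausible movement that
            # no speed/angle filter could (or should) see
            idx = []
            candidates = list(range(2, n - 2))
            rng.shuffle(candidates)
            for j in candidates:
                if len(idx) >= config.n_spike_fixes:
                    break
                if any(abs(j - k) <= 2 for k in idx):
                    continue
                if "Z" in (lc[j - 1], lc[j], lc[j + 1]):
                    continue
                idx.append(j)
            for j in idx:
                track_brg = np.arctan2(y[j + 1] - y[j - 1],
                                       x[j + 1] - x[j - 1])
                side = rng.choice([-1.0, 1.0])
                r = 35.0 + rng.uniform(0, 15.0)
                x[j] += r * np.cos(track_brg + side * np.pi / 2)
                y[j] += r * np.sin(track_brg + side * np.pi / 2)
                artifact[j] = True
        lon, lat = proj.inverse(x, y)
        fixes.append(pd.DataFrame({
            "animal_id": animal, "time": tr.time.to_numpy(),
            "lon": lon, "lat": lat, "lc": lc, "artifact": artifact}))
    return pd.concat(fixes, ignore_index=True)


def simulate_track(config: SimConfig, start=DEFAULT_START):
    """Simulate latent paths and observed Argos fixes for all animals.

    Returns ``(fixes, truth)``; the latent path, haul-out intervals, patch
    geometry and per-animal classes live in the :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_by_class = np.floor(np.asarray(config.class_mix) * config.n_animals).astype(int)
    while n_by_class.sum() < config.n_animals:
        n_by_class[int(np.argmax(np.asarray(config.class_mix)))] += 1
    classes = [c for c, n in zip(ANIMAL_CLASSES, n_by_class) for _ in range(n)]
    latents, hls, animal_classes = [], [], {}
    for i, cls in enumerate(classes):
        animal = f"hs{i:02d}"
        animal_classes[animal] = cls
        tr, hdf = _simulate_latent_one(animal, config, rng, start)
        latents.append(tr)
        hls.append(hdf)
    latent = pd.concat(latents, ignore_index=True)
    haulouts = pd.concat(hls, ignore_index=True)
    fixes = _observe_argos(latent, config, rng)
    drift_by_day = {a: {d: config.condition_trajectory(float(d))
                        for d in range(int(np.ceil(config.duration_days)) + 1)}
                    for a in animal_classes}
    patches = [(c[0], c[1], config.patch_radius_km, config.patch_dwell_factor)
               for c in config.patch_centers]
    truth = GroundTruth(latent_track=latent, patches=patches,
                        drift_rate_by_day=drift_by_day, haulouts=haulouts,
                        animal_classes=animal_classes)
    return fixes, truth


# ---------------------------------------------------------------------------
# dives

def _interp_latent(tr: pd.DataFrame, t_hr: np.ndarray):
    lon = np.interp(t_hr, tr.t_hr.to_numpy(), tr.lon.to_numpy())
    lat = np.interp(t_hr, tr.t_hr.to_numpy(), tr.lat.to_numpy())
    idx = np.clip(np.searchsorted(tr.t_hr.to_numpy(), t_hr), 0, len(tr) - 1)
    mode = tr["mode"].to_numpy()[idx]
    return lon, lat, mode


def _u_profile(duration_s, max_depth, rd, ra, rng):
    """U-shaped 6-point profile; bottom wiggles too flat/brief to mimic drift."""
    t_desc = max_depth / rd
    t_asc = max_depth / ra
    if t_desc + t_asc > 0.85 * duration_s:
        duration_s = (t_desc + t_asc) / 0.7
    t1, t4 = t_desc, duration_s - t_asc
    t2 = t1 + (t4 - t1) / 3.0
    t3 = t1 + 2.0 * (t4 - t1) / 3.0
    d2 = max_depth * rng.uniform(0.96, 1.0)
    d3 = max_depth * rng.uniform(0.96, 1.0)
    ts = np.array([0.0, t1, t2, t3, t4, duration_s])
    ds = np.array([0.0, max_depth, d2, d3, max_depth, 0.0])
    return ts, ds


def _v_profile(duration_s, max_depth):
    ts = np.array([0.0, 0.25, 0.5, 0.65, 0.8, 1.0]) * duration_s
    ds = np.array([0.0, 0.5, 1.0, 0.7, 0.4, 0.0]) * max_depth
    return ts, ds


def _sloping_bottom_profile(duration_s, max_depth, rd, ra, rng):
    """Benthic-style dive whose long mid-segment slopes gently.

    Passes the drift-candidate duration/rate screen but is an active dive —
    the negatives the drift classifier must learn to reject.
    """
    t_desc = max_depth / rd
    t_asc = max_depth / ra
    if t_desc + t_asc > 0.5 * duration_s:
        duration_s = (t_desc + t_asc) / 0.4
    t1, t4 = t_desc, duration_s - t_asc
    slope = rng.uniform(0.02, 0.18) * rng.choice([-1.0, 1.0])
    t2 = t1 + 0.1 * (t4 - t1)
    t3 = t1 + 0.9 * (t4 - t1)
    d2 = max_depth * rng.uniform(0.9, 1.0)
    d3 = float(np.clip(d2 + slope * (t3 - t2), 10.0, max_depth))
    ts = np.array([0.0, t1, t2, t3, t4, duration_s])
    ds = np.array([0.0, max_depth, d2, d3, max_depth * rng.uniform(0.85, 1.0),
                   0.0])
    return ts, ds


def _drift_profile(duration_s, drift_rate, rng, bathy_m):
    """Descent, long passive drift segment (points 1->2), brief hold, ascent."""
    slope = -drift_rate                      # m/s, positive = sinking
    T = duration_s
    rd = max(rng.normal(1.0, 0.15), 0.5)
    ra = max(rng.normal(0.9, 0.12), 0.5)
    d1 = rng.uniform(150.0, 300.0)
    if bathy_m < 350.0:
        d1 = rng.uniform(0.3, 0.5) * bathy_m
    if d1 / rd > 0.25 * T:
        d1 = 0.25 * T * rd
    t1 = d1 / rd
    t2 = t1 + 0.4 * T
    d2 = float(np.clip(d1 + slope * (t2 - t1), 10.0, max(bathy_m - 10.0, 20.0)))
    t3 = t1 + 0.46 * T
    d4 = d2 * rng.uniform(0.92, 1.0)
    t_asc = d4 / ra
    total = max(T, t3 + 0.02 * T + t_asc)
    t4 = total - t_asc
    ts = np.array([0.0, t1, t2, t3, t4, total])
    ds = np.array([0.0, d1, d2, d2, d4, 0.0])
    realized = -(ds[2] - ds[1]) / (ts[2] - ts[1])
    return ts, ds, realized


def simulate_dives(truth: GroundTruth, config: SimConfig, bathy: EnvGrid,
                   start=DEFAULT_START, rng=None) -> pd.DataFrame:
    """Simulate compressed dive records along the latent tracks.

    Dive depth/duration distributions are class-conditional; dives inside
    patches carry elevated transit rates (the vertical foraging signal), and
    drift dives (probability ``drift_dive_prob``) embed a passive segment
    whose rate follows the condition trajectory.  Ground-truth columns
    ``is_drift``, ``true_drift_rate`` and ``in_patch`` are included.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    records = []
    for animal, tr in truth.latent_track.groupby("animal_id", sort=False):
        cls = truth.animal_classes[animal]
        med_d, sig_d, med_dur, sig_dur = DIVE_PARAMS[cls]
        t_hr = float(tr.t_hr.iloc[0])
        end_hr = float(tr.t_hr.iloc[-1])
        k = 0
        while t_hr < end_hr:
            gap_min = config.dive_interval_min * rng.uniform(0.8, 1.2)
            t_hr += gap_min / 60.0
            lon, lat, mode = _interp_latent(tr, np.array([t_hr]))
            if mode[0] == "haulout" or t_hr >= end_hr:
                continue
            lonf, latf = float(lon[0]), float(lat[0])
            bat = bathy.nearest_fast(lonf, latf)
            in_patch = mode[0] == "ars"
            day = t_hr / 24.0
            is_drift = rng.uniform() < config.drift_dive_prob
            if is_drift:
                dur = float(np.clip(rng.normal(14.7, 4.0), 8.0, 40.0)) * 60.0
                rate_true = (config.condition_trajectory(day)
                             + rng.normal(0, config.drift_rate_noise_sd))
                ts, ds, realized = _drift_profile(dur, rate_true, rng, bat)
                rate_true = realized
            else:
                rate_true = np.nan
                maxd = float(np.exp(rng.normal(np.log(med_d), sig_d)))
                for _ in range(5):
                    if maxd <= bat - 5.0:
                        break
                    logger.debug("dive deeper than bathymetry; resampling")
                    maxd = float(np.exp(rng.normal(np.log(med_d), sig_d)))
                maxd = float(np.clip(maxd, 10.0, max(bat - 5.0, 10.0)))
                dur = float(np.exp(rng.normal(np.log(med_dur), sig_dur))) * 60.0
                elev = config.in_patch_rate_elevation_sd if in_patch else 0.0
                rd = max(rng.normal(0.9 + 0.15 * elev, 0.15), 0.3)
                ra = max(rng.normal(0.8 + 0.12 * elev, 0.12), 0.3)
                shape = rng.uniform()
                if shape < 0.15:
                    ts, ds = _v_profile(max(dur, 2 * maxd / rd), maxd)
                elif shape < 0.35:
                    ts, ds = _sloping_bottom_profile(dur, maxd, rd, ra, rng)
                else:
                    ts, ds = _u_profile(dur, maxd, rd, ra, rng)
            dur = float(ts[-1])
            surf = float(np.exp(rng.normal(np.log(SURFACE_PARAMS[cls]), 0.3)))
            start_time = start + pd.to_timedelta(t_hr, unit="h")
            rec = {"dive_id": f"{animal}_{k:05d}", "animal_id": animal,
                   "class": cls, "start_time": start_time,
                   "end_time": start_time + pd.to_timedelta(dur, unit="s"),
                   "duration_s": dur, "max_depth_m": float(ds.max()),
                   "post_surface_s": surf, "is_drift": is_drift,
                   "true_drift_rate": rate_true, "in_patch": in_patch}
            for j in range(6):
                rec[f"t_{j}"] = float(ts[j])
                rec[f"d_{j}"] = float(ds[j])
            records.append(rec)
            t_hr += (dur + surf) / 3600.0
            k += 1
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# CTD casts

def simulate_ctd(truth: GroundTruth, config: SimConfig, sst: EnvGrid,
                 start=DEFAULT_START, rng=None,
                 noise_sd: float = 0.1) -> pd.DataFrame:
    """One 17-point CTD cast per 6-hour window along each latent track.

    The shallowest (6 m) temperature equals the SST raster value at that
    position/date plus N(0, noise_sd); deeper points relax toward a cold
    deep layer.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    rows = []
    for animal, tr in truth.latent_track.groupby("animal_id", sort=False):
        span_hr = float(tr.t_hr.iloc[-1]) - float(tr.t_hr.iloc[0])
        n_prof = int(span_hr // 6.0)
        for w in range(n_prof):
            t_hr = float(tr.t_hr.iloc[0]) + (w + 0.5) * 6.0
            lon, lat, _mode = _interp_latent(tr, np.array([t_hr]))
            time = start + pd.to_timedelta(t_hr, unit="h")
            surf = sst.nearest_fast(float(lon[0]), float(lat[0]), time=time)
            deep = 0.5
            blend = np.exp(-(CTD_DEPTHS - CTD_DEPTHS[0]) / 150.0)
            temps = surf * blend + deep * (1.0 - blend)
            temps = temps + rng.normal(0, noise_sd, len(CTD_DEPTHS))
            if noise_sd == 0:
                temps[0] = surf
            for z, tc in zip(CTD_DEPTHS, temps):
                rows.append((animal, time, float(lon[0]), float(lat[0]),
                             float(z), float(tc)))
    return pd.DataFrame(rows, columns=["animal_id", "time", "lon", "lat",
                                       "depth_m", "temp_C"])


# ---------------------------------------------------------------------------
# synthetic modelling tables with known habitat response

def synthetic_daily_records(n_animals: int = 6, n_trips: int = 2,
                            n_days: int = 30,
                            sst_effect=lambda z: 0.5 * z * z,
                            bathy_effect=lambda z: 0.0 * z,
                            animal_sd: float = 0.3, trip_sd: float = 0.1,
                            noise_sd: float = 0.3, response: str = "index",
                            seed: int = 0) -> pd.DataFrame:
    """DailyRecord-style table with known smooth habitat effects.

    The response is ``sst_effect(z_sst) + bathy_effect(z_bathy) + animal
    intercept + trip intercept + noise`` where z are the standardized
    covariates; used to validate the additive-mixed-model recovery and the
    AIC structure selection.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        a_id = f"hs{a:02d}"
        a_eff = rng.normal(0, animal_sd)
        for t in range(n_trips):
            t_id = f"{a_id}_t{t + 1}"
            t_eff = rng.normal(0, trip_sd)
            sst = rng.normal(4.0, 2.5, n_days)
            bathy = rng.normal(1800.0, 900.0, n_days)
            for d in range(n_days):
                rows.append((a_id, t_id, "all",
                             pd.Timestamp("2008-04-01") + pd.Timedelta(days=d),
                             sst[d], bathy[d], a_eff + t_eff))
    df = pd.DataFrame(rows, columns=["animal_id", "trip_id", "class", "day",
                                     "sst_C", "bathymetry_m", "re_eff"])
    z_sst = (df.sst_C - df.sst_C.mean()) / df.sst_C.std(ddof=0)
    z_bat = (df.bathymetry_m - df.bathymetry_m.mean()) / df.bathymetry_m.std(ddof=0)
    df["true_smooth_sst"] = sst_effect(z_sst.to_numpy())
    df["true_smooth_bathy"] = bathy_effect(z_bat.to_numpy())
    df[response] = (df.true_smooth_sst + df.true_smooth_bathy + df.re_eff
                    + rng.normal(0, noise_sd, len(df)))
    return df


# ---------------------------------------------------------------------------
# orchestration and writers

def simulate_dataset(config: SimConfig, start=DEFAULT_START) -> SrdlDataset:
    """Full synthetic SRDL bundle: rasters, fixes, dives, CTD, truth."""
    bathy, ice, sst = make_rasters(config, start)
    fixes, truth = simulate_track(config, start)
    rng = np.random.default_rng(config.seed + 1)
    dives = simulate_dives(truth, config, bathy, start, rng)
    ctd = simulate_ctd(truth, config, sst, start,
                       np.random.default_rng(config.seed + 2))
    return SrdlDataset(fixes=fixes, dives=dives, ctd=ctd,
                       haulouts=truth.haulouts, truth=truth,
                       bathymetry=bathy, ice=ice, sst=sst, config=config)


def write_dataset(ds: SrdlDataset, outdir) -> None:
    """Write the bundle as CSVs + truth JSON + NetCDF rasters."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.fixes.to_csv(out / "fixes.csv", index=False)
    ds.dives.to_csv(out / "dives.csv", index=False)
    ds.ctd.to_csv(out / "ctd.csv", index=False)
    ds.haulouts.to_csv(out / "haulouts.csv", index=False)
    ds.truth.latent_track.to_csv(out / "latent_track.csv", index=False)
    truth = {
        "patches": [list(p) for p in ds.truth.patches],
        "animal_classes": ds.truth.animal_classes,
        "drift_rate_by_day": {a: {str(k): v for k, v in d.items()}
                              for a, d in ds.truth.drift_rate_by_day.items()},
        "config": ds.config.to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    save_grid(ds.bathymetry, out / "bathymetry.nc")
    save_grid(ds.ice, out / "ice.nc")
    save_grid(ds.sst, out / "sst.nc")
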