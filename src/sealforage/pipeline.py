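"""End-to-end orchestration: simulate -> clean -> indexes -> daily table -> models.

The pipeline output of record is the DailyRecord table: one row per animal
and UTC calendar day joining the three daily foraging indexes (mean FPT,
transit-rate index, drift-rate change) with daily environmental means
(bathymetry, SST, ice) and the daily mean maximum dive depth.  The habitat
models consume this table.  The join for modelling is inner on
(animal, day); a full outer audit table with per-source presence flags is
also produced so join losses are accountable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dives as dv
from . import drift as dr
from . import envgrid as env
from . import fpt as fp
from . import tracks as tk
from . import transit as tx
from .config import SimConfig
from .synthetic import SrdlDataset, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs in one validated bundle."""

    sim: SimConfig = field(default_factory=SimConfig)
    interval_hr: float = 1.0
    spacing_km: float = 5.0
    radii_km: tuple = (5.0, 100.0, 5.0)      # start, stop, step
    fpt_quantile: float = 0.75
    weight_exponent: float = 2.0
    transit_variant: str = "per_dive"
    min_dive_depth_m: float = 10.0
    sst_gap_hr: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if not 0 < self.fpt_quantile < 1:
            raise ValueError("fpt_quantile must be in (0, 1)")
        if self.spacing_km <= 0 or self.interval_hr <= 0:
            raise ValueError("spacing_km and interval_hr must be positive")

    def radii(self) -> np.ndarray:
        a, b, s = self.radii_km
        return np.arange(a, b + 1e-9, s)


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Run every stage on a fresh synthetic dataset; returns the bundle."""
    config.validate()
    config.sim.seed = config.seed
    ds = simulate_dataset(config.sim)
    bundle = process_dataset(ds, config)
    if outdir is not None:
        write_bundle(bundle, config, outdir)
    return bundle


def process_dataset(ds: SrdlDataset, config: RunConfig) -> dict:
    """All analysis stages on an existing dataset (synthetic or loaded)."""
    classes = ds.truth.animal_classes
    fixes = tk.sda_filter(ds.fixes)
    track = tk.smooth_track(fixes, ds.haulouts, interval_hr=config.interval_hr,
                            error_sd_by_lc=ds.config.argos_error_sd_by_lc)
    track = tk.segment_seasons(track, classes, ds.haulouts)
    points, trips = tk.segment_trips(track, classes,
                                     center=ds.config.deployment_center)

    # --- FPT index -----------------------------------------------------
    trip_points = [points[points.trip_id == t].copy()
                   for t in trips.trip_id if (points.trip_id == t).sum() >= 2]
    resampled = []
    for tp in trip_points:
        try:
            rs = fp.resample_track_equidistant(tp, config.spacing_km)
        except ValueError:
            continue
        if len(rs) >= 3:
            rs["trip_id"] = tp.trip_id.iloc[0]
            resampled.append(rs)
    scale_km, var_curve = fp.select_ars_scale(resampled, config.radii())
    fpt_pts = []
    for rs in resampled:
        vals = fp.fpt_at_radius(rs, scale_km)
        out = rs.copy()
        out["fpt_hr"] = vals
        fpt_pts.append(out)
    fpt_points = pd.concat(fpt_pts, ignore_index=True)
    haul_pos = haulout_positions(ds.truth.latent_track, ds.haulouts)
    fpt_points = fp.exclude_haulout_fpt(fpt_points, ds.haulouts, haul_pos,
                                        scale_km)
    dfpt = fp.daily_fpt(fpt_points)
    flags = fp.foraging_days(dfpt, q=config.fpt_quantile) if len(dfpt) >= 4 \
        else dfpt.assign(foraging=False)

    # --- dive metrics and transit index --------------------------------
    dives = dv.geolocate_dives(ds.dives, track)
    dives = dv.attach_context(dives, points)
    rates = dv.compute_transit_rates(dives, config.min_dive_depth_m)
    pca = tx.fit_transit_pca(rates)
    scored = tx.score_dives(rates, pca, config.weight_exponent)
    dti = tx.daily_transit_index(scored, config.transit_variant)

    # --- drift condition ------------------------------------------------
    cands = dr.extract_drift_candidates(dives)
    labels = cands.dive_id.map(dives.set_index("dive_id").is_drift) \
        if "is_drift" in dives else pd.Series(False, index=cands.index)
    clf = dr.DriftClassifier(random_state=config.seed)
    drift_parts = []
    spline_fits = []
    if len(cands) >= 10:
        clf.fit(cands, labels.to_numpy())
        cands = dr.weight_candidates(cands, clf, config.weight_exponent)
        cands = dr.screen_positive_drifts(cands)
        cands = cands.merge(dives[["dive_id", "trip_id"]], on="dive_id",
                            how="left")
        for t in trips.itertuples():
            seg = cands[cands.trip_id == t.trip_id]
            dur = (t.end_time - t.start_time).total_seconds() / 86400.0
            if not dr.trip_inclusion(dur, len(seg)) or len(seg) < 4:
                continue
            try:
                fit = dr.fit_drift_spline(seg, t.trip_id, t.start_time,
                                          t.end_time)
            except ValueError as e:
                logger.info("drift spline skipped: %s", e)
                continue
            d = fit.daily.copy()
            d["animal_id"] = t.animal_id
            d["trip_id"] = t.trip_id
            spline_fits.append(fit)
            drift_parts.append(d)
    daily_drift = (pd.concat(drift_parts, ignore_index=True) if drift_parts
                   else pd.DataFrame(columns=["animal_id", "day",
                                              "predicted_rate",
                                              "daily_change", "trip_id"]))

    # --- environment -----------------------------------------------------
    dive_env = env.attach_dive_env(dives, ds.bathymetry, ds.ice, ds.ctd,
                                   max_gap_hr=config.sst_gap_hr)
    denv = env.daily_env(dive_env)
    ddepth = dv.daily_mean_max_depth(dives)

    daily = assemble_daily(dfpt, dti, daily_drift, denv, ddepth, points,
                           classes)
    return {
        "dataset": ds, "fixes": fixes, "track": points, "trips": trips,
        "ars_scale_km": scale_km, "var_curve": var_curve,
        "fpt_points": fpt_points, "daily_fpt": dfpt, "foraging_flags": flags,
        "pca": pca, "scored_dives": scored, "daily_transit": dti,
        "drift_candidates": cands, "drift_classifier": clf,
        "drift_splines": spline_fits, "daily_drift": daily_drift,
        "dive_env": dive_env, "daily_env": denv, "daily_depth": ddepth,
        "daily_records": daily["inner"], "daily_audit": daily["audit"],
    }


def haulout_positions(latent: pd.DataFrame, haulouts: pd.DataFrame) -> pd.DataFrame:
    """Mean position of the track within each haul-out interval."""
    rows = []
    for h in haulouts.itertuples():
        seg = latent[(latent.animal_id == h.animal_id)
                     & (latent.time >= h.start) & (latent.time <= h.end)]
        if len(seg):
            rows.append((h.animal_id, seg.lon.mean(), seg.lat.mean()))
    return pd.DataFrame(rows, columns=["animal_id", "lon", "lat"])


def assemble_daily(dfpt, dti, daily_drift, denv, ddepth, points, classes):
    """Join the three indexes + env + depth on (animal, day); audit losses."""
    parts = {
        "fpt": dfpt.rename(columns={"daily_fpt_hr": "fpt_hr"})
                   [["animal_id", "day", "fpt_hr"]],
        "transit": dti[["animal_id", "day", "transit_index"]],
        "drift": daily_drift.rename(columns={"daily_change": "drift_change"})
                            [["animal_id", "day", "drift_change"]]
        if len(daily_drift) else
        pd.DataFrame(columns=["animal_id", "day", "drift_change"]),
        "env": denv,
        "depth": ddepth[["animal_id", "day", "mean_max_depth"]],
    }
    audit = None
    for name, df in parts.items():
        df = df.copy()
        df["day"] = pd.to_datetime(df["day"])
        audit = df if audit is None else audit.merge(
            df, on=["animal_id", "day"], how="outer")
    audit["animal_class"] = audit.animal_id.map(classes)
    season = points.copy()
    season["day"] = season.time.dt.floor("D")
    smap = (season.groupby(["animal_id", "day"]).season
            .agg(lambda s: s.mode().iloc[0]).rename("season").reset_index())
    audit = audit.merge(smap, on=["animal_id", "day"], how="left")
    tmap = (season.dropna(subset=["trip_id"])
            .groupby(["animal_id", "day"]).trip_id
            .agg(lambda s: s.mode().iloc[0]).rename("trip_id").reset_index())
    audit = audit.merge(tmap, on=["animal_id", "day"], how="left")
    audit["trip_id"] = audit.trip_id.fillna(audit.animal_id + "_no_trip")
    core = ["fpt_hr", "transit_index", "drift_change", "bathymetry_m", "sst_C"]
    inner = audit.dropna(subset=[c for c in core if c in audit]).copy()
    logger.info("daily join: %d audit rows -> %d complete rows",
                len(audit), len(inner))
    return {"inner": inner.reset_index(drop=True), "audit": audit}


def write_bundle(bundle: dict, config: RunConfig, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = ["fixes", "track", "trips", "var_curve", "fpt_points",
              "daily_fpt", "foraging_flags", "scored_dives", "daily_transit",
              "drift_candidates", "daily_drift", "dive_env", "daily_env",
              "daily_depth", "daily_records", "daily_audit"]
    manifest = {"seed": config.seed, "ars_scale_km": bundle["ars_scale_km"],
                "row_counts": {}}
    for name in tables:
        obj = bundle.get(name)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
            manifest["row_counts"][name] = len(obj)
    manifest["pca_variance_explained"] = float(
        bundle["pca"].variance_explained)
    cfg = {k: v for k, v in vars(config).items() if k != "sim"}
    cfg["sim"] = config.sim.to_dict()
    (out / "resolved_config.json").write_text(json.dumps(cfg, indent=1,
                                                         default=str))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))


def make_fixtures(seed: int = 0, outdir=None) -> SrdlDataset:
    """Deterministic small bundle (3 animals, 60 days) for tests and demos."""
    cfg = SimConfig(n_animals=3, class_mix=(1 / 3, 1 / 3, 1 / 3),
                    duration_days=60.0, seed=seed)
    ds = simulate_dataset(cfg)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds
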