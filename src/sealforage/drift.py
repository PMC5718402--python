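"""Drift-dive detection and the drift-rate body-condition index.

During a drift dive the animal stops swimming and drifts vertically at a
rate set by its buoyancy, hence its lipid store: lean animals sink (negative
rate), fat animals rise.  The pipeline is: (1) scan each compressed profile
for candidate passive segments; (2) score each candidate with a random
forest trained on labelled dives; (3) screen out isolated positive-rate
segments (rare, influential, usually artefacts); (4) per trip, fit a
weighted smoothing spline to the segment rates — weights combine the
0-100 m depth curve with the classifier probability — constrained to the
observed rate envelope; (5) report daily predicted rates and their first
difference, the daily change in drift rate, as the body-condition index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.ensemble import RandomForestClassifier

from .dives import D_COLS, T_COLS
from .transit import depth_weight

logger = logging.getLogger(__name__)

#: candidate thresholds: min fraction of dive duration, |rate| window (m/s)
MIN_DURATION_FRACTION = 0.30
RATE_WINDOW = (0.01, 1.2)

FEATURES = ["dur_frac", "abs_rate", "rate_contrast", "depth_span",
            "dive_duration_s", "max_depth_m"]


def extract_drift_candidates(dives: pd.DataFrame,
                             min_frac: float = MIN_DURATION_FRACTION,
                             rate_window=RATE_WINDOW) -> pd.DataFrame:
    """Candidate passive segments from the 5 inter-point legs of each dive.

    A leg qualifies if it is not the first (descent) or last (ascent) leg,
    lasts at least ``min_frac`` of the dive, and has |vertical rate| inside
    ``rate_window``.  ``drift_rate`` is signed with negative = sinking.
    """
    t = dives[T_COLS].to_numpy(float)
    d = dives[D_COLS].to_numpy(float)
    dt = np.diff(t, axis=1)                     # (n, 5)
    dd = np.diff(d, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(dt > 0, dd / dt, np.nan)   # m/s, positive = down
    dur = dives.duration_s.to_numpy(float)[:, None]
    frac = dt / np.maximum(dur, 1e-9)
    ok = np.zeros_like(slope, dtype=bool)
    ok[:, 1:4] = True                           # interior legs only
    ok &= frac >= min_frac
    ok &= (np.abs(slope) >= rate_window[0]) & (np.abs(slope) <= rate_window[1])
    rows = []
    n_idx, s_idx = np.where(ok)
    for i, j in zip(n_idx, s_idx):
        r = dives.iloc[i]
        rates_all = slope[i][np.isfinite(slope[i])]
        contrast = float(np.abs(slope[i, j] - np.nanmedian(rates_all))) \
            if len(rates_all) else 0.0
        rows.append({
            "dive_id": r.dive_id, "animal_id": r.animal_id,
            "segment": int(j),
            "start_time": r.start_time + pd.to_timedelta(t[i, j], unit="s"),
            "duration_s": float(dt[i, j]),
            "dur_frac": float(frac[i, j]),
            "drift_rate": float(-slope[i, j]),
            "abs_rate": float(np.abs(slope[i, j])),
            "rate_contrast": contrast,
            "mean_depth": float((d[i, j] + d[i, j + 1]) / 2.0),
            "depth_span": float(np.abs(dd[i, j])),
            "dive_duration_s": float(dur[i, 0]),
            "max_depth_m": float(r.max_depth_m),
        })
    cols = ["dive_id", "animal_id", "segment", "start_time", "duration_s",
            "dur_frac", "drift_rate", "abs_rate", "rate_contrast",
            "mean_depth", "depth_span", "dive_duration_s", "max_depth_m"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class DriftClassifier:
    """Random forest giving each candidate a drift probability.

    Semi-supervised in the sense that the training labels come from the
    simulator's ground truth, optionally augmented with hand-labelled
    examples.  A dive with no candidate segments has probability 0 by
    definition.
    """

    n_estimators: int = 200
    random_state: int = 0
    model: RandomForestClassifier | None = field(default=None, repr=False)

    def fit(self, candidates: pd.DataFrame, labels: np.ndarray) -> "DriftClassifier":
        X = candidates[FEATURES].to_numpy(float)
        y = np.asarray(labels, dtype=int)
        self.model = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state,
            min_samples_leaf=2)
        self.model.fit(X, y)
        return self

    def predict_proba(self, candidates: pd.DataFrame) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier not fitted; call fit() first")
        if candidates.empty:
            return np.array([])
        X = candidates[FEATURES].to_numpy(float)
        classes = self.model.classes_
        p = self.model.predict_proba(X)
        if len(classes) == 1:
            return np.full(len(X), float(classes[0]))
        return p[:, int(np.argmax(classes))]

    def save(self, path) -> None:
        import joblib
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "DriftClassifier":
        import joblib
        return joblib.load(path)


def weight_candidates(candidates: pd.DataFrame, clf: DriftClassifier,
                      weight_exponent: float = 2.0) -> pd.DataFrame:
    """Depth weight x classification probability = combined weight."""
    out = candidates.copy()
    out["depth_weight"] = depth_weight(out.mean_depth.to_numpy(), weight_exponent)
    out["classifier_probability"] = clf.predict_proba(out)
    out["combined_weight"] = out.depth_weight * out.classifier_probability
    return out


def screen_positive_drifts(segments: pd.DataFrame, k: int = 2,
                           window_days: float = 5.0) -> pd.DataFrame:
    """Flag isolated positive-rate segments for exclusion.

    A positive (rising) segment is kept only when at least ``k`` other
    positive segments from the same animal fall within ``window_days``;
    otherwise it is excluded pending manual review (``needs_review``).
    """
    out = segments.copy()
    out["positive"] = out.drift_rate > 0
    excluded = np.zeros(len(out), dtype=bool)
    for animal, grp in out[out.positive].groupby("animal_id"):
        t_days = grp.start_time.values.astype("datetime64[ns]").astype("int64") \
            / 1e9 / 86400.0
        for i, (idx, ti) in enumerate(zip(grp.index, t_days)):
            n_near = int(np.sum(np.abs(t_days - ti) <= window_days)) - 1
            if n_near < k:
                excluded[out.index.get_loc(idx)] = True
    out["excluded_positive"] = excluded
    out["needs_review"] = out.positive
    return out


def trip_inclusion(trip_duration_days: float, n_segments: int) -> bool:
    """One or more identified drift segments per 2 days of trip."""
    return n_segments >= trip_duration_days / 2.0


@dataclass
class DriftSplineFit:
    trip_id: str
    lam: float
    daily: pd.DataFrame          # day, predicted_rate, daily_change
    envelope: tuple[float, float]


def fit_drift_spline(segments: pd.DataFrame, trip_id: str,
                     trip_start: pd.Timestamp, trip_end: pd.Timestamp,
                     envelope_pad: float = 0.05,
                     lam: float | None = None) -> DriftSplineFit:
    """Weighted constrained smoothing spline of drift rate over a trip.

    Cubic smoothing spline with the penalty chosen by generalized
    cross-validation; observation weights are the combined depth x
    classifier weights.  The fitted curve is constrained to the observed
    drift-rate envelope +- ``envelope_pad`` m/s.  Daily rates are evaluated
    at UTC-day midpoints; the daily change is the finite first difference
    (central, one-sided at the ends).
    """
    keep = segments.combined_weight > 0
    if "excluded_positive" in segments:
        keep &= ~segments.excluded_positive
    seg = segments[keep].copy()
    if len(seg) < 4:
        raise ValueError(f"trip {trip_id}: need >= 4 weighted segments")
    x = (seg.start_time - trip_start).dt.total_seconds().to_numpy() / 86400.0
    y = seg.drift_rate.to_numpy(float)
    w = seg.combined_weight.to_numpy(float)
    # merge duplicate abscissae by weighted mean (keeps the fit invariant to
    # splitting one observation into two at half weight)
    order = np.argsort(x)
    x, y, w = x[order], y[order], w[order]
    ux, inv = np.unique(np.round(x, 9), return_inverse=True)
    wsum = np.bincount(inv, weights=w)
    ymean = np.bincount(inv, weights=w * y) / wsum
    try:
        spl = make_smoothing_spline(ux, ymean, w=wsum, lam=lam)
        lam_used = float(lam) if lam is not None else np.nan
    except Exception:
        logger.warning("trip %s: GCV spline failed; refitting with lam=1",
                       trip_id)
        spl = make_smoothing_spline(ux, ymean, w=wsum, lam=1.0)
        lam_used = 1.0
    lo, hi = float(y.min()) - envelope_pad, float(y.max()) + envelope_pad
    days = pd.date_range(trip_start.floor("D"), trip_end.floor("D"), freq="D")
    mid = (days + pd.Timedelta(hours=12) - trip_start).total_seconds() / 86400.0
    mid_clip = np.clip(mid, ux[0], ux[-1])      # no extrapolation beyond data
    pred = np.clip(spl(mid_clip), lo, hi)
    change = np.gradient(pred) if len(pred) > 1 else np.zeros(1)
    daily = pd.DataFrame({"day": days, "predicted_rate": pred,
                          "daily_change": change})
    return DriftSplineFit(trip_id=trip_id, lam=lam_used, daily=daily,
                          envelope=(lo, hi))
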