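"""Trip-level movement descriptors, circular statistics, and group tests.

The azimuth of a trip is the initial great-circle bearing from its first
point to its most distant point (clockwise from north); its cosine and sine
separate the north-south and east-west components.  Trip directionality is
tested with a Rayleigh test; class/season contrasts use two-sided
Wilcoxon-Mann-Whitney tests (exact for small untied samples).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import geo

logger = logging.getLogger(__name__)


def trip_summary(points: pd.DataFrame, complete: bool = True) -> dict:
    """Azimuth, max distance and duration for one trip's ordered points.

    Azimuth is reported for every trip; distance and duration are reported
    only for complete trips (NaN otherwise).  Ties for the most distant
    point break to the earliest time.
    """
    if len(points) < 2:
        raise ValueError("degenerate single-point trip")
    pts = points.sort_values("time")
    lon0, lat0 = float(pts.lon.iloc[0]), float(pts.lat.iloc[0])
    d = geo.haversine_km(pts.lon.to_numpy(), pts.lat.to_numpy(), lon0, lat0)
    imax = int(np.argmax(d))                     # argmax returns first max
    az = geo.initial_bearing_deg(lon0, lat0,
                                 float(pts.lon.iloc[imax]),
                                 float(pts.lat.iloc[imax]))
    dur_days = (pts.time.iloc[-1] - pts.time.iloc[0]).total_seconds() / 86400.0
    return {
        "azimuth_deg": az,
        "cos_azimuth": math.cos(math.radians(az)),
        "sin_azimuth": math.sin(math.radians(az)),
        "max_distance_km": float(d[imax]) if complete else np.nan,
        "duration_days": dur_days if complete else np.nan,
        "complete": complete,
    }


def summarize_trips(points: pd.DataFrame, trips: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for t in trips.itertuples():
        pts = points[points.trip_id == t.trip_id]
        if len(pts) < 2:
            continue
        s = trip_summary(pts, complete=bool(t.complete))
        s.update(trip_id=t.trip_id, animal_id=t.animal_id,
                 season=t.season, animal_class=getattr(t, "_3", None))
        rows.append(s)
    df = pd.DataFrame(rows)
    if not df.empty and "class" in trips:
        df["animal_class"] = df.trip_id.map(trips.set_index("trip_id")["class"])
    return df


def rayleigh_test(azimuths_deg) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: (mean resultant length, p).

    p uses the standard large-sample approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - n R^2)) - (1 + 2n)) with R = n * R_bar.
    """
    a = np.radians(np.asarray(azimuths_deg, dtype=float))
    n = len(a)
    if n < 3:
        raise ValueError("need >= 3 azimuths")
    C, S = np.cos(a).sum(), np.sin(a).sum()
    R = math.hypot(C, S)
    r_bar = R / n
    z = R * R / n
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n * n - R * R)) - (1 + 2 * n))
    p = min(p, 1.0)
    return r_bar, p


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test: (U, p).

    Exact for small untied samples (total n <= 20, no ties); the normal
    approximation with tie correction otherwise.  All-tied inputs yield
    p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("all values tied across both groups; p = 1")
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(pvals, method: str = "holm") -> np.ndarray:
    """Optional multiple-comparison adjustment for the comparison tables.

    Raw pairwise p-values are the default reporting; this is an opt-in
    correction (``holm`` or ``bonferroni``).
    """
    from statsmodels.stats.multitest import multipletests
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unsupported method {method!r}")
    return multipletests(np.asarray(pvals, dtype=float), method=method)[1]


def foraging_dive_behavior(daily_depth: pd.DataFrame, daily_env: pd.DataFrame,
                           flags: pd.DataFrame) -> pd.DataFrame:
    """Depth use on flagged foraging days: mean max depth and its ratio to
    bathymetry (daily means).  Days with missing/zero bathymetry are
    skipped; ratios above 1 are kept but flagged inconsistent.
    """
    f = flags[flags.foraging][["animal_id", "day"]]
    df = f.merge(daily_depth, on=["animal_id", "day"], how="inner")
    df = df.merge(daily_env[["animal_id", "day", "bathymetry_m"]],
                  on=["animal_id", "day"], how="inner")
    bad = ~np.isfinite(df.bathymetry_m) | (df.bathymetry_m <= 0)
    if bad.any():
        logger.warning("%d foraging days lack bathymetry; skipped", int(bad.sum()))
    df = df[~bad].copy()
    df["depth_over_bathymetry"] = df.mean_max_depth / df.bathymetry_m
    df["ratio_inconsistent"] = df.depth_over_bathymetry > 1.0
    if df.ratio_inconsistent.any():
        logger.warning("%d days have depth/bathymetry > 1",
                       int(df.ratio_inconsistent.sum()))
    return df
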