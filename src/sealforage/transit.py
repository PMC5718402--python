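"""Vertical transit-rate foraging-intensity index.

Descent and ascent rates rise jointly when a diver maximizes bottom time
over a prey patch, so their first principal component — after per-variable
standardization — serves as a dimensionless "foraging intensity" score per
dive.  Because lung air dominates buoyancy above ~100 m and contaminates
the rates, each score is down-weighted by a nonlinear function of the mean
transit depth: weight 0 at 0 m rising to 1 at 100 m (and 1 beyond).  Scores
are averaged per UTC animal-day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PcaModel:
    """Standardization constants plus axis-1 loadings of the 2-rate PCA."""

    means: np.ndarray       # (descent, ascent) means
    sds: np.ndarray
    loadings: np.ndarray    # unit-norm, both components positive
    variance_explained: float

    def score(self, rates: pd.DataFrame) -> np.ndarray:
        z = (rates[["descent_rate", "ascent_rate"]].to_numpy(float)
             - self.means) / self.sds
        return z @ self.loadings


def fit_transit_pca(rates: pd.DataFrame) -> PcaModel:
    """PCA of standardized (descent, ascent) pairs; axis 1 sign-fixed positive."""
    X = rates[["descent_rate", "ascent_rate"]].to_numpy(float)
    X = X[np.isfinite(X).all(axis=1)]
    if len(X) < 10:
        raise ValueError("need >= 10 dives with finite rates")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for name, s in zip(("descent_rate", "ascent_rate"), sds):
        if s == 0:
            raise ValueError(f"{name} has zero variance; PCA undefined")
    Z = (X - means) / sds
    cov = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    load = evecs[:, -1]
    if load.sum() < 0:
        load = -load
    if not (load > 0).all():
        # perfectly anti-correlated rates: orient the larger component positive
        load = np.abs(load)
        load = load / np.linalg.norm(load)
    return PcaModel(means=means, sds=sds, loadings=load,
                    variance_explained=float(evals[-1] / evals.sum()))


def depth_weight(depth_m, exponent: float = 2.0):
    """Nonlinear 0-100 m weighting: w(d) = (d/100)^exponent, w(d>=100)=1.

    The quadratic default is the simplest smooth monotone curve through the
    two fixed endpoints w(0)=0 and w(100)=1; the exponent is configurable.
    """
    d = np.asarray(depth_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative transit depth")
    w = np.where(d >= 100.0, 1.0, (d / 100.0) ** exponent)
    return w if w.ndim else float(w)


def score_dives(rates: pd.DataFrame, model: PcaModel,
                weight_exponent: float = 2.0) -> pd.DataFrame:
    """Per-dive PC1 scores, depth weights, and weighted contributions."""
    out = rates.copy()
    out["pc1_score"] = model.score(rates)
    out["depth_weight"] = depth_weight(rates.mean_transit_depth.to_numpy(),
                                       weight_exponent)
    out["weighted_score"] = out.pc1_score * out.depth_weight
    return out


def daily_transit_index(scored: pd.DataFrame,
                        variant: str = "per_dive") -> pd.DataFrame:
    """Daily index per UTC animal-day.

    ``variant="per_dive"`` (default) divides the summed weighted scores by
    the dive count; ``variant="weighted_mean"`` divides by the summed
    weights (days with all-zero weight get index 0).
    """
    df = scored.copy()
    df["day"] = df.start_time.dt.floor("D")
    g = df.groupby(["animal_id", "day"])
    if variant == "per_dive":
        idx = g.weighted_score.mean()
    elif variant == "weighted_mean":
        num = g.weighted_score.sum()
        den = g.depth_weight.sum()
        idx = (num / den.where(den > 0)).fillna(0.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    out = idx.rename("transit_index").reset_index()
    out["n_dives"] = g.size().to_numpy()
    return out
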