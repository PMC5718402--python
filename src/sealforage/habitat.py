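"""Additive mixed habitat models for the daily foraging indexes.

Each daily foraging index (FPT, transit index, drift-rate change) is
modelled per season against standardized bathymetry and SST with
(optionally class-specific) spline smooths, a class main effect, and
Gaussian random intercepts for animal and for trip within animal.  All
combinations of smooth terms are fitted and ranked by AIC; among candidate
models within two AIC units the most parsimonious is selected.

Smooths are cubic regression splines with a fixed modest basis dimension
(default 5, i.e. 4 free columns after sum-to-zero centering); the small
basis acts as the regularizer.  Models are estimated by maximum likelihood
(statsmodels MixedLM) so AICs are comparable across fixed-effect
structures.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# covariate preparation

def standardize(df: pd.DataFrame, columns) -> tuple[pd.DataFrame, dict]:
    """Centre/scale columns to mean 0, SD 1; returns the invertible transform."""
    out = df.copy()
    transform = {}
    for c in columns:
        v = out[c].to_numpy(float)
        if not np.isfinite(v).all():
            raise ValueError(f"column {c!r} has non-finite values")
        mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            raise ValueError(f"column {c!r} is constant; cannot standardize")
        out[c + "_std"] = (v - mu) / sd
        transform[c] = (mu, sd)
    return out, transform


def unstandardize(z, column: str, transform: dict):
    mu, sd = transform[column]
    return np.asarray(z) * sd + mu


def check_collinearity(df: pd.DataFrame, columns, threshold: float = 0.8):
    """Pairwise Pearson screen; fails listing pairs with |r| > threshold."""
    if len(columns) < 2:
        raise ValueError("need >= 2 covariates")
    bad = []
    for a, b in itertools.combinations(columns, 2):
        r = float(np.corrcoef(df[a].to_numpy(float), df[b].to_numpy(float))[0, 1])
        if abs(r) > threshold:
            bad.append((a, b, r))
    pairs = pd.DataFrame(bad, columns=["var_a", "var_b", "pearson_r"])
    return len(bad) == 0, pairs


# ---------------------------------------------------------------------------
# spline basis

def _bspline_knots(x: np.ndarray, k: int) -> np.ndarray:
    n_interior = k - 4
    qs = np.linspace(0, 1, n_interior + 2)[1:-1] if n_interior > 0 else []
    interior = np.quantile(x, qs) if len(qs) else np.array([])
    lo, hi = float(x.min()), float(x.max())
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _bspline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    B = BSpline.design_matrix(xc, knots, 3, extrapolate=False).toarray()
    return B


def _smooth_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Centred basis with one column dropped (sum-to-zero identifiability)."""
    B = _bspline_basis(x, knots)
    B = B - B.mean(axis=0)
    return B[:, :-1]


# ---------------------------------------------------------------------------
# model spec / fit containers

@dataclass(frozen=True)
class ModelSpec:
    response: str
    smooth_terms: tuple = ()          # covariate names (raw, un-suffixed)
    by_class: bool = True
    class_effect: bool = True
    season: str | None = None
    k: int = 5

    def label(self) -> str:
        parts = ["1"]
        for t in self.smooth_terms:
            parts.append(f"s({t},by=class)" if self.by_class else f"s({t})")
        if self.class_effect:
            parts.append("class")
        return "+".join(parts)


@dataclass
class GammFit:
    spec: ModelSpec
    aic: float
    adjusted_r2: float
    n_params: int
    transform: dict
    knots: dict = field(repr=False, default_factory=dict)
    coef: dict = field(repr=False, default_factory=dict)     # name -> beta
    cov: object = field(repr=False, default=None)
    col_names: dict = field(repr=False, default_factory=dict)
    fittedvalues: np.ndarray = field(repr=False, default=None)
    re_sd: dict = field(default_factory=dict)
    result: object = field(repr=False, default=None)

    def smooth_curve(self, term: str, cls: str | None = None,
                     n: int = 100) -> pd.DataFrame:
        """Fitted smooth on the standardized scale with pointwise ~95% CIs."""
        knots = self.knots[term]
        grid = np.linspace(knots[0], knots[-1], n)
        X = _smooth_columns_from_stats(grid, knots, self._basis_means[term])
        names = self.col_names[(term, cls)]
        beta = np.array([self.coef[c] for c in names])
        fit = X @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X,
                               self.cov.loc[names, names].to_numpy(), X))
        raw = unstandardize(grid, term, self.transform)
        return pd.DataFrame({"x_std": grid, "x_raw": raw, "fit": fit,
                             "se": se, "lo": fit - 1.96 * se,
                             "hi": fit + 1.96 * se})

    def smooth_values(self, term: str, x_std: np.ndarray,
                      cls: str | None = None) -> np.ndarray:
        X = _smooth_columns_from_stats(np.asarray(x_std, float),
                                       self.knots[term],
                                       self._basis_means[term])
        names = self.col_names[(term, cls)]
        beta = np.array([self.coef[c] for c in names])
        return X @ beta

    _basis_means: dict = field(repr=False, default_factory=dict)


def _smooth_columns_from_stats(x, knots, means):
    B = _bspline_basis(np.asarray(x, float), knots)
    B = B - means
    return B[:, :-1]


# ---------------------------------------------------------------------------
# fitting

def fit_gamm(table: pd.DataFrame, spec: ModelSpec) -> GammFit:
    """Fit one additive mixed model on a DailyRecord table.

    ``table`` needs the response column, raw covariate columns named in
    ``spec.smooth_terms``, and animal_id / trip_id / class columns.
    Covariates are standardized internally; the transform is stored.
    """
    df = table.copy()
    if spec.season is not None:
        df = df[df.season == spec.season].copy()
    classes = sorted(df["class"].unique()) if "class" in df else ["all"]
    if spec.by_class and spec.smooth_terms and len(classes) < 2 and \
            spec.class_effect:
        raise ValueError("class-specific terms with a single class")
    use_class = len(classes) > 1
    df, transform = standardize(df, list(spec.smooth_terms))

    knots, basis_means, col_names = {}, {}, {}
    design_cols = []
    for term in spec.smooth_terms:
        x = df[term + "_std"].to_numpy(float)
        kn = _bspline_knots(x, spec.k)
        B_full = _bspline_basis(x, kn)
        means = B_full.mean(axis=0)
        knots[term] = kn
        basis_means[term] = means
        Bc = (B_full - means)[:, :-1]
        if spec.by_class and use_class:
            for cls in classes:
                ind = (df["class"] == cls).to_numpy(float)
                names = []
                for j in range(Bc.shape[1]):
                    nm = f"s_{_safe(term)}_{_safe(cls)}_{j}"
                    df[nm] = Bc[:, j] * ind
                    names.append(nm)
                col_names[(term, cls)] = names
                design_cols.extend(names)
        else:
            names = []
            for j in range(Bc.shape[1]):
                nm = f"s_{_safe(term)}_{j}"
                df[nm] = Bc[:, j]
                names.append(nm)
            col_names[(term, None)] = names
            design_cols.extend(names)

    rhs = ["1"]
    if spec.class_effect and use_class:
        rhs.append("C(Q('class'))")
    rhs.extend(design_cols)
    formula = f"Q('{spec.response}') ~ " + " + ".join(rhs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["animal_id"],
                            re_formula="1",
                            vc_formula={"trip": "0 + C(trip_id)"})
        res = model.fit(reml=False, method="lbfgs", maxiter=300)
    fe = res.fe_params
    n = len(df)
    n_fixed = len(fe)
    n_params = n_fixed + 2 + 1          # + animal & trip variances + residual
    fitted = np.asarray(res.fittedvalues)
    y = df[spec.response].to_numpy(float)
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - n_fixed - 1, 1)
    aic = float(-2.0 * res.llf + 2.0 * n_params)
    cov = res.cov_params().loc[fe.index, fe.index]
    fit = GammFit(spec=spec, aic=aic, adjusted_r2=float(adj),
                  n_params=n_params, transform=transform, knots=knots,
                  coef=dict(fe), cov=cov, col_names=col_names,
                  fittedvalues=fitted,
                  re_sd={"animal": float(np.sqrt(max(res.cov_re.iloc[0, 0], 0))),
                         "trip": float(np.sqrt(max(res.vcomp[0], 0)))
                         if len(res.vcomp) else 0.0},
                  result=res)
    fit._basis_means = basis_means
    return fit


def _safe(s) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in str(s))


def enumerate_specs(response: str, covariates=("bathymetry_m", "sst_C"),
                    by_class: bool = True, class_effect: bool = True,
                    season: str | None = None, k: int = 5):
    """Power set of smooth terms (the 'all combinations of metrics' grid)."""
    specs = []
    for r in range(len(covariates) + 1):
        for terms in itertools.combinations(covariates, r):
            specs.append(ModelSpec(response=response, smooth_terms=terms,
                                   by_class=by_class,
                                   class_effect=class_effect,
                                   season=season, k=k))
    return specs


def select_model(fits: list[GammFit]) -> GammFit:
    """AIC selection with the parsimony rule.

    Candidates are fits within 2 AIC units of the best; among them the one
    with the fewest parameters wins, ties broken by lower AIC then by term
    label order.
    """
    if not fits:
        raise ValueError("no fits to select from")
    best_aic = min(f.aic for f in fits)
    cand = [f for f in fits if f.aic - best_aic < 2.0]
    cand.sort(key=lambda f: (f.n_params, f.aic, f.spec.label()))
    chosen = cand[0]
    logger.info("selected %s (AIC %.1f, %d params) among %d candidates",
                chosen.spec.label(), chosen.aic, chosen.n_params, len(cand))
    return chosen
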