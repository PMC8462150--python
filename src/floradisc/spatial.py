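"""Province-level discovery patterns.

Per-province summaries (mean and range-size-weighted mean discovery year),
a permutation null for "earlier/later than expected" discovery, Moran's I
spatial autocorrelation over the contiguity graph, and the two explanatory
regressions: OLS for mean discovery year and logit-link beta regression for
inventory completeness, both with backward AIC model selection over [0,1]-
standardized predictors.

The permutation null shuffles the vector of description years across species
while holding every species' province occupancy (and hence the weights,
the inverse range sizes) fixed: a province's standardized score

    z = (observed - mean(null)) / sd(null)

is positive when its flora was described later than the country-wide
description sequence would predict given which species occur there.
|z| > 1.96 is the conventional flag.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ProvinceTable, SpeciesRecord
from .survival import step_select_aic

SIG_THRESHOLD = 1.96


def _incidence(catalog: Sequence[SpeciesRecord], provinces: ProvinceTable):
    codes = provinces.codes
    code_ix = {c: i for i, c in enumerate(codes)}
    A = np.zeros((len(codes), len(catalog)))
    for j, r in enumerate(catalog):
        for c in r.provinces:
            A[code_ix[c], j] = 1.0
    return A, codes


def summarize_provinces(
    catalog: Sequence[SpeciesRecord],
    provinces: ProvinceTable,
    completeness: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-province species counts and mean discovery years.

    The weighted mean uses w_i = 1/range_size so widespread species do not
    dominate every province they touch.  Provinces with no species keep NaN
    means and are flagged for exclusion from the regressions.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    A, codes = _incidence(catalog, provinces)
    years = np.array([r.description_year for r in catalog], dtype=float)
    w = np.array([1.0 / len(r.provinces) for r in catalog])
    n_sp = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_year = (A @ years) / n_sp
        wmean_year = (A @ (w * years)) / (A @ w)
    mean_year[n_sp == 0] = np.nan
    wmean_year[n_sp == 0] = np.nan
    if (n_sp == 0).any():
        empty = [codes[i] for i in np.flatnonzero(n_sp == 0)]
        warnings.warn(
            f"province(s) with no species, means undefined: {empty}",
            RuntimeWarning, stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "n_species": n_sp.astype(int),
            "mean_discovery_year": mean_year,
            "weighted_mean_discovery_year": wmean_year,
        },
        index=pd.Index(codes, name="code"),
    )
    out = out.join(provinces.frame)
    out["coastal"] = out["coastal"].astype(int)
    if completeness is not None:
        out["completeness"] = completeness.reindex(out.index)
    return out


def standardized_discovery_time(
    catalog: Sequence[SpeciesRecord],
    provinces: ProvinceTable,
    n_shuffles: int = 1000,
    seed: int | None = None,
    method: str = "sample",
    threshold: float = SIG_THRESHOLD,
) -> pd.DataFrame:
    """Range-size-weighted standardized mean discovery time per province.

    ``method="sample"`` draws ``n_shuffles`` uniform permutations of the
    description-year vector; ``"exact"`` enumerates all n! assignments
    (guarded to n <= 9) so small cases can be checked exactly.  Provinces
    whose null SD is zero (e.g., all years identical) get NaN z and are
    flagged.
    """
    if len(catalog) < 2:
        raise ValueError("need at least two species to shuffle")
    A, codes = _incidence(catalog, provinces)
    years = np.array([r.description_year for r in catalog], dtype=float)
    w = np.array([1.0 / len(r.provinces) for r in catalog])
    Aw = A * w
    denom = Aw.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = (Aw @ years) / denom

    if method == "exact":
        n = len(years)
        if math.factorial(n) > 400000:
            raise ValueError("exact enumeration limited to small catalogs")
        perms = np.array(list(itertools.permutations(years)))
        null = (Aw @ perms.T) / denom[:, None]
        n_used = perms.shape[0]
    elif method == "sample":
        rng = np.random.default_rng(seed)
        Y = np.empty((len(years), n_shuffles))
        for k in range(n_shuffles):
            Y[:, k] = rng.permutation(years)
        null = (Aw @ Y) / denom[:, None]
        n_used = n_shuffles
    else:
        raise ValueError(f"unknown method {method!r}")

    null_mean = null.mean(axis=1)
    null_sd = null.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - null_mean) / null_sd
    degenerate = (null_sd == 0) | ~np.isfinite(null_sd)
    z = np.where(degenerate, np.nan, z)
    if degenerate.any():
        warnings.warn(
            f"zero null SD, z undefined for: {[codes[i] for i in np.flatnonzero(degenerate)]}",
            RuntimeWarning, stacklevel=2,
        )
    return pd.DataFrame(
        {
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "significant": np.abs(z) > threshold,
            "n_shuffles": n_used,
        },
        index=pd.Index(codes, name="code"),
    )


@dataclass
class MoranResult:
    I: float
    expected: float
    p_permutation: float
    n: int
    permutations: int


def morans_i(
    values: pd.Series,
    provinces: ProvinceTable,
    permutations: int = 999,
    seed: int | None = None,
    standardize: str = "row",
) -> MoranResult:
    """Moran's I over the province contiguity graph.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with binary contiguity
    weights, row-standardized by default.  NaN provinces are dropped (with
    their incident edges); the permutation p-value is two-sided around the
    expectation -1/(n-1).
    """
    vals = values.dropna()
    keep = list(vals.index)
    n = len(keep)
    if n < 3:
        raise ValueError("need at least three provinces with values")
    ix = {c: i for i, c in enumerate(keep)}
    W = np.zeros((n, n))
    for a in keep:
        for b in provinces.neighbors[a]:
            if b in ix:
                W[ix[a], ix[b]] = 1.0
    if standardize == "row":
        rs = W.sum(axis=1, keepdims=True)
        isolated = rs[:, 0] == 0
        if isolated.any():
            warnings.warn("isolated province(s) in contiguity graph",
                          RuntimeWarning, stacklevel=2)
        W = np.divide(W, np.where(rs == 0, 1.0, rs))
    elif standardize != "binary":
        raise ValueError(f"unknown weight standardization {standardize!r}")

    x = vals.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant values: Moran's I undefined (zero variance)")

    def _I(v):
        z = v - v.mean()
        return (n / W.sum()) * float(z @ W @ z) / float(z @ z)

    I_obs = _I(x)
    expected = -1.0 / (n - 1)
    p = float("nan")
    if permutations > 0:
        rng = np.random.default_rng(seed)
        dev = np.empty(permutations)
        for k in range(permutations):
            dev[k] = _I(rng.permutation(x))
        extreme = np.sum(np.abs(dev - expected) >= abs(I_obs - expected) - 1e-15)
        p = (extreme + 1.0) / (permutations + 1.0)
    return MoranResult(I=float(I_obs), expected=expected, p_permutation=p,
                       n=n, permutations=permutations)


@dataclass
class RegressionFit:
    """Selected explanatory regression (OLS or beta family)."""

    family: str
    selected_terms: list
    summary: pd.DataFrame  # coefficient, ci_lower, ci_upper, se, p
    fit_statistic: float  # adjusted R^2 (ols) or pseudo R^2 (beta)
    phi: float | None  # beta precision, None for OLS
    aic: float
    aic_trace: list
    residuals: pd.Series
    model_result: object  # underlying statsmodels results


def _standardize_terms(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for t in terms:
        col = df[t].astype(float)
        if set(col.dropna().unique()) <= {0.0, 1.0}:
            X[t] = col
        else:
            lo, hi = col.min(), col.max()
            if hi == lo:
                raise ValueError(f"term {t!r} is constant")
            X[t] = (col - lo) / (hi - lo)
    return X


def fit_ols_step(
    summary: pd.DataFrame,
    response: str = "mean_discovery_year",
    terms: Sequence[str] = ("n_species", "coastal", "pop_density", "area_km2",
                            "centroid_lon", "centroid_lat"),
) -> RegressionFit:
    """OLS of a province summary on [0,1]-standardized predictors with
    backward AIC selection; residuals are exported so the caller can run the
    Moran's I spatial-independence check on them."""
    import statsmodels.api as sm

    data = summary.dropna(subset=[response])
    if len(data) < len(terms) + 2:
        raise ValueError("need at least two more provinces than candidate terms")
    y = data[response].astype(float)
    X = _standardize_terms(data, terms)

    def fit_fn(subset):
        exog = sm.add_constant(X[list(subset)], has_constant="add")
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design")
        res = sm.OLS(y, exog).fit()
        return res, float(res.aic)

    res, selected, trace = step_select_aic(list(terms), fit_fn)
    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "coefficient": res.params,
            "ci_lower": ci[0],
            "ci_upper": ci[1],
            "se": res.bse,
            "p": res.pvalues,
        }
    )
    return RegressionFit(
        family="ols",
        selected_terms=list(selected),
        summary=table,
        fit_statistic=float(res.rsquared_adj),
        phi=None,
        aic=float(res.aic),
        aic_trace=trace,
        residuals=pd.Series(res.resid, index=data.index),
        model_result=res,
    )


def _squeeze_unit(y: np.ndarray) -> np.ndarray:
    """Boundary compression (y (n-1) + 0.5) / n, applied when any response
    touches 0 or 1."""
    n = len(y)
    if ((y <= 0) | (y >= 1)).any():
        y = (np.clip(y, 0, 1) * (n - 1) + 0.5) / n
    return y


def fit_beta_step(
    summary: pd.DataFrame,
    response: str = "completeness",
    terms: Sequence[str] = ("n_species", "coastal", "pop_density", "area_km2",
                            "centroid_lon", "centroid_lat"),
) -> RegressionFit:
    """Logit-link beta regression (ML) of a proportion response with
    backward AIC selection.

    Pseudo R^2 is the squared correlation between the linear predictor and
    logit(observed).  The precision parameter phi is reported on the natural
    scale.  A (near-)constant response makes phi diverge; this is raised
    rather than reported.
    """
    import statsmodels.api as sm
    from statsmodels.othermod.betareg import BetaModel

    data = summary.dropna(subset=[response])
    if len(data) < len(terms) + 2:
        raise ValueError("need at least two more provinces than candidate terms")
    y = _squeeze_unit(data[response].astype(float).to_numpy())
    if np.ptp(y) < 1e-12:
        raise ValueError("constant response: beta precision diverges")
    X = _standardize_terms(data, terms)

    def fit_fn(subset):
        exog = sm.add_constant(X[list(subset)], has_constant="add")
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design")
        model = BetaModel(y, exog)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False, maxiter=500)
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError("beta fit produced non-finite parameters")
        retvals = getattr(res, "mle_retvals", {}) or {}
        if retvals and not retvals.get("converged", True):
            gnorm = np.linalg.norm(model.score(res.params))
            raise RuntimeError(f"beta regression did not converge "
                               f"(gradient norm {gnorm:.3g})")
        k = len(res.params)
        aic = -2.0 * float(res.llf) + 2.0 * k
        return res, aic

    res, selected, trace = step_select_aic(list(terms), fit_fn)
    ci = res.conf_int()
    k_mean = res.model.exog.shape[1]
    names = list(res.model.exog_names[:k_mean]) + ["precision"]
    table = pd.DataFrame(
        {
            "coefficient": np.asarray(res.params),
            "ci_lower": np.asarray(ci)[:, 0],
            "ci_upper": np.asarray(ci)[:, 1],
            "se": np.asarray(res.bse),
            "p": np.asarray(res.pvalues),
        },
        index=names[: len(res.params)],
    )
    linpred = res.model.exog @ np.asarray(res.params)[:k_mean]
    logit_y = np.log(y / (1 - y))
    pseudo_r2 = float(np.corrcoef(linpred, logit_y)[0, 1] ** 2)
    phi = float(np.exp(np.asarray(res.params)[-1]))
    aic = -2.0 * float(res.llf) + 2.0 * len(res.params)
    mean_resid = y - 1.0 / (1.0 + np.exp(-linpred))
    return RegressionFit(
        family="beta",
        selected_terms=list(selected),
        summary=table,
        fit_statistic=pseudo_r2,
        phi=phi,
        aic=aic,
        aic_trace=trace,
        residuals=pd.Series(mean_resid, index=data.index),
        model_result=res,
    )
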