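"""Distribution alignment of numeric variables, optionally per group, plus
covariate residualization.

All transforms fit their parameters on non-missing entries only and leave
missing entries missing.  When a ``group_key`` is given the transform is fit
and applied independently within each group — the difference between joint
and group-wise scaling is itself analytically interesting: group-wise
scaling removes between-group location/scale differences, which can mask
real subgroup structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EHRFrame
from .errors import ValidationError

__all__ = ["NormalizationRecord", "normalize", "regress_out"]

METHODS = ("log", "maxabs", "minmax", "power", "quantile", "robust_scale",
           "scale", "offset")


@dataclass
class NormalizationRecord:
    """Method name and fitted parameters, sufficient to reproduce the
    transform exactly on the same data; per-group parameters when a group
    key was used."""

    method: str
    group_key: str | None
    parameters: dict = field(default_factory=dict)  # group -> var -> params


def _scale_col(col, params=None):
    obs = col[~np.isnan(col)]
    if params is None:
        mu = float(obs.mean())
        sd = float(obs.std(ddof=0))  # population convention
        params = {"mean": mu, "sd": sd}
    mu, sd = params["mean"], params["sd"]
    if sd == 0:
        warnings.warn("constant column under scale; output set to 0")
        return np.where(np.isnan(col), np.nan, 0.0), params
    return (col - mu) / sd, params


def _minmax_col(col, params=None):
    obs = col[~np.isnan(col)]
    if params is None:
        params = {"min": float(obs.min()), "max": float(obs.max())}
    lo, hi = params["min"], params["max"]
    if hi == lo:
        return np.where(np.isnan(col), np.nan, 0.0), params
    return (col - lo) / (hi - lo), params


def _maxabs_col(col, params=None):
    obs = col[~np.isnan(col)]
    if params is None:
        params = {"maxabs": float(np.max(np.abs(obs)))}
    m = params["maxabs"]
    if m == 0:
        return col.copy(), params
    return col / m, params


def _offset_col(col, params=None):
    obs = col[~np.isnan(col)]
    if params is None:
        params = {"offset": float(obs.min())}
    return col - params["offset"], params


def _log_col(col, params=None, offset: float = 0.0):
    if params is None:
        params = {"offset": offset}
    shifted = col + params["offset"]
    if np.nanmin(shifted) <= -1:
        raise ValidationError(
            "log normalization needs values > -1 after offset "
            "(log1p convention)")
    return np.log1p(shifted), params


def _robust_col(col, params=None):
    obs = col[~np.isnan(col)]
    if params is None:
        q1, med, q3 = np.percentile(obs, [25, 50, 75])
        params = {"median": float(med), "iqr": float(q3 - q1)}
    if params["iqr"] == 0:
        return np.where(np.isnan(col), np.nan, 0.0), params
    return (col - params["median"]) / params["iqr"], params


def _power_col(col, params=None):
    obs = col[~np.isnan(col)]
    if params is None:
        lam = float(stats.yeojohnson_normmax(obs))
        params = {"lambda": lam}
    out = col.copy()
    m = ~np.isnan(col)
    out[m] = stats.yeojohnson(col[m], lmbda=params["lambda"])
    # standardize after the transform, matching common practice
    mu, sd = float(out[m].mean()), float(out[m].std(ddof=0))
    params.setdefault("mean", mu)
    params.setdefault("sd", sd if sd > 0 else 1.0)
    out[m] = (out[m] - params["mean"]) / params["sd"]
    return out, params


def _quantile_block(M: np.ndarray):
    """Map each column to the across-column mean order-statistic profile.

    Ranks use averaged ties; the reference profile is the mean of each
    column's empirical quantile function on a common grid.
    """
    n, p = M.shape
    grid = np.linspace(0, 1, n)
    profiles = []
    for j in range(p):
        obs = np.sort(M[~np.isnan(M[:, j]), j])
        if obs.size == 0:
            raise ValidationError("all-missing column in quantile "
                                  "normalization")
        profiles.append(np.quantile(obs, grid, method="linear"))
    reference = np.mean(profiles, axis=0)
    out = np.full_like(M, np.nan)
    for j in range(p):
        m = ~np.isnan(M[:, j])
        vals = M[m, j]
        ranks = stats.rankdata(vals, method="average")
        q = (ranks - 1) / max(len(vals) - 1, 1)
        out[m, j] = np.interp(q, grid, reference)
    return out, {"reference": reference.tolist()}


def normalize(frame: EHRFrame, method: str, variables=None,
              group_key: str | None = None, log_offset: float = 0.0):
    """Apply a normalization method to numeric variables.

    Methods
    -------
    log
        log1p of the (optionally offset) values.
    maxabs, minmax, robust_scale, scale, offset
        Classic per-variable rescalings; ``scale`` uses the population
        (1/n) standard deviation.
    power
        Yeo-Johnson transform with maximum-likelihood lambda, then
        standardized.
    quantile
        Maps every targeted variable onto the shared mean order-statistic
        profile.

    ``group_key`` names a categorical obs column; the transform is then fit
    and applied separately within each group.
    """
    if method not in METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    new = frame.copy()
    variables = list(variables) if variables is not None \
        else new.numeric_var_names()
    M, names = new.numeric_matrix(variables)
    if group_key is None:
        group_labels = np.array(["__all__"] * new.n_obs, dtype=object)
    else:
        if group_key not in new.obs.columns:
            raise KeyError(group_key)
        group_labels = np.array([str(v) for v in new.obs[group_key]],
                                dtype=object)
    record = NormalizationRecord(method, group_key, {})
    for g in sorted(set(group_labels)):
        rows = group_labels == g
        sub = M[rows]
        gparams: dict = {}
        if method == "quantile":
            sub, gparams = _quantile_block(sub)
        else:
            fn = {"log": lambda c, p=None: _log_col(c, p, log_offset),
                  "maxabs": _maxabs_col, "minmax": _minmax_col,
                  "power": _power_col, "robust_scale": _robust_col,
                  "scale": _scale_col, "offset": _offset_col}[method]
            for j, name in enumerate(names):
                sub[:, j], gparams[name] = fn(sub[:, j])
        M[rows] = sub
        record.parameters[g] = gparams
    new.set_numeric_matrix(M, names)
    new.uns["ehrkit"].setdefault("normalization", []).append(
        {"method": method, "group_key": group_key, "variables": list(names)})
    return new, record


def regress_out(frame: EHRFrame, covariates, variables=None) -> EHRFrame:
    """Replace variables by residuals of an OLS fit on obs covariates.

    An intercept is always included; rank-deficient covariate matrices fall
    back to the pseudo-inverse with a warning.  Rows with a missing value or
    covariate are left missing.
    """
    covariates = list(covariates)
    new = frame.copy()
    cov_cols = []
    for c in covariates:
        if c in new.obs.columns:
            vals = pd.to_numeric(pd.Series(new.obs[c].to_numpy()),
                                 errors="coerce").to_numpy(dtype=float)
        elif c in new.var_names:
            vals = np.array([np.nan if pd.isna(v) else float(v)
                             for v in new.get_values(c)])
        else:
            raise KeyError(c)
        cov_cols.append(vals)
    C = np.column_stack([np.ones(new.n_obs)] + cov_cols)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        warnings.warn("rank-deficient covariates; using pseudo-inverse")
    variables = list(variables) if variables is not None \
        else [v for v in new.numeric_var_names() if v not in covariates]
    M, names = new.numeric_matrix(variables)
    for j in range(M.shape[1]):
        y = M[:, j]
        ok = ~np.isnan(y) & ~np.isnan(C).any(axis=1)
        if ok.sum() <= C.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(C[ok], y[ok], rcond=None)
        M[ok, j] = y[ok] - C[ok] @ beta
    new.set_numeric_matrix(M, names)
    return new
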