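"""Quality control: missingness metrics, Little's MCAR test, value hygiene,
bias detection and sampling utilities.

Little's test compares, for each distinct missingness pattern, the observed
variable means against the grand means estimated by expectation-maximization
under a multivariate normal model.  The resulting statistic

    d^2 = sum_j  m_j (ybar_oj - mu_oj)' Sigma_oj^{-1} (ybar_oj - mu_oj)

is asymptotically chi-squared with sum_j p_j - p degrees of freedom, where
pattern j has m_j rows observing p_j of the p variables.  The null
hypothesis is that missingness is completely at random (MCAR); rejection
indicates the observed-data means differ across patterns, as happens under
missingness that depends on observed values (MAR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EHRFrame
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "QCMetrics", "MCARTestResult", "BiasReport",
    "qc_metrics", "summarize_features", "winsorize", "clip_features",
    "little_mcar_test", "detect_bias", "subsample", "balanced_sample",
]


# ---------------------------------------------------------------------------
# missingness metrics
# ---------------------------------------------------------------------------

@dataclass
class QCMetrics:
    """Per-variable and per-observation missingness plus numeric summaries."""

    var_table: pd.DataFrame   # missing_count, missing_fraction, min/max/mean/sd
    obs_table: pd.DataFrame   # missing_count, missing_fraction
    total_missing: int


def _missing_mask(frame: EHRFrame) -> np.ndarray:
    return pd.isna(pd.DataFrame(frame.X)).to_numpy()


def qc_metrics(frame: EHRFrame) -> QCMetrics:
    """Count missing entries per variable and per observation.

    Also writes ``missing_count``/``missing_fraction`` into the frame's var
    and obs tables and min/max/mean/sd of non-missing values for
    numeric-valued variables into the var table.
    """
    mask = _missing_mask(frame)
    n_obs, n_vars = frame.shape
    var_missing = mask.sum(axis=0).astype(int)
    obs_missing = mask.sum(axis=1).astype(int)
    var_tbl = pd.DataFrame({
        "missing_count": var_missing,
        "missing_fraction": var_missing / n_obs if n_obs else 0.0,
    }, index=frame.var_names)
    mins = np.full(n_vars, np.nan)
    maxs = np.full(n_vars, np.nan)
    means = np.full(n_vars, np.nan)
    sds = np.full(n_vars, np.nan)
    numeric = frame.numeric_var_names()
    if numeric:
        M, names = frame.numeric_matrix(numeric)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for name, col in zip(names, M.T):
                j = frame.col_index(name)
                mins[j] = np.nanmin(col) if np.isfinite(col).any() else np.nan
                maxs[j] = np.nanmax(col) if np.isfinite(col).any() else np.nan
                means[j] = np.nanmean(col)
                sds[j] = np.nanstd(col, ddof=1) if np.isfinite(col).sum() > 1 \
                    else np.nan
    var_tbl["min"], var_tbl["max"] = mins, maxs
    var_tbl["mean"], var_tbl["sd"] = means, sds
    obs_tbl = pd.DataFrame({
        "missing_count": obs_missing,
        "missing_fraction": obs_missing / n_vars if n_vars else 0.0,
    }, index=frame.obs_names)
    for c in var_tbl.columns:
        frame.var[c] = var_tbl[c].to_numpy()
    for c in obs_tbl.columns:
        frame.obs[c] = obs_tbl[c].to_numpy()
    return QCMetrics(var_tbl, obs_tbl, int(mask.sum()))


def summarize_features(frame: EHRFrame, groupby: str,
                       statistics=("min", "max", "mean")) -> EHRFrame:
    """Collapse repeated per-patient measurements to summary statistics.

    Produces one observation per level of the obs column ``groupby``; every
    numeric variable ``v`` is replaced by columns ``v_min``/``v_max``/
    ``v_mean`` (as requested) over its non-missing values.  A group with no
    observed value for a variable gets the missing marker.
    """
    if groupby not in frame.obs.columns:
        raise KeyError(groupby)
    statistics = list(statistics)
    bad = set(statistics) - {"min", "max", "mean"}
    if bad:
        raise ValueError(f"unsupported statistics {sorted(bad)}")
    numeric = frame.numeric_var_names()
    if set(numeric) != set(frame.var_names):
        raise ValidationError("summarize_features requires numeric variables")
    M, names = frame.numeric_matrix(numeric)
    df = pd.DataFrame(M, columns=names)
    df[groupby] = frame.obs[groupby].to_numpy()
    agg = df.groupby(groupby, sort=True).agg(statistics)
    agg.columns = [f"{v}_{s}" for v, s in agg.columns]
    order = [f"{v}_{s}" for v in names for s in statistics]
    agg = agg[order]
    X = agg.to_numpy(dtype=np.float64)
    var = pd.DataFrame({"kind": "numeric", "encoding_state": "raw"},
                       index=pd.Index(agg.columns))
    obs = pd.DataFrame({groupby: agg.index.astype(str)},
                       index=pd.Index(agg.index.astype(str)))
    return EHRFrame(X, obs, var, uns=frame.uns)


# ---------------------------------------------------------------------------
# value hygiene
# ---------------------------------------------------------------------------

def winsorize(frame: EHRFrame, variables=None,
              limits=(0.05, 0.05)) -> EHRFrame:
    """Cap extreme values at the given lower/upper quantiles.

    ``limits`` are tail fractions in [0, 0.5).  Quantiles use the
    order-statistic convention (lower cap: smallest value at or above the
    lower quantile position; upper cap: largest value at or below the upper
    position), so caps are actual data values and the operation is exactly
    idempotent.  Missing entries are untouched.
    """
    lo, hi = float(limits[0]), float(limits[1])
    if not (0 <= lo < 0.5 and 0 <= hi < 0.5):
        raise ValueError("winsorize limits must lie in [0, 0.5)")
    new = frame.copy()
    variables = list(variables) if variables is not None \
        else new.numeric_var_names()
    M, names = new.numeric_matrix(variables)
    for k, name in enumerate(names):
        col = M[:, k]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        lower = np.quantile(obs, lo, method="higher")
        upper = np.quantile(obs, 1 - hi, method="lower")
        M[:, k] = np.clip(col, lower, upper)
    new.set_numeric_matrix(M, names)
    return new


def clip_features(frame: EHRFrame, variables=None,
                  bounds: dict | tuple = (-np.inf, np.inf)) -> EHRFrame:
    """Clamp values into explicit per-variable [low, high] bounds.

    ``bounds`` is either a single (low, high) pair applied to all requested
    variables or a map variable -> (low, high).  Returns the new frame; the
    number of modified entries is recorded in ``uns['ehrkit']['clipped']``.
    """
    new = frame.copy()
    variables = list(variables) if variables is not None \
        else new.numeric_var_names()
    if not isinstance(bounds, dict):
        bounds = {name: tuple(bounds) for name in variables}
    n_modified = 0
    M, names = new.numeric_matrix(variables)
    for k, name in enumerate(names):
        low, high = bounds.get(name, (-np.inf, np.inf))
        if low > high:
            raise ValueError(f"inverted bounds for {name!r}")
        col = M[:, k]
        with np.errstate(invalid="ignore"):
            n_modified += int(np.nansum((col < low) | (col > high)))
        M[:, k] = np.clip(col, low, high)
    new.set_numeric_matrix(M, names)
    new.uns["ehrkit"]["clipped"] = n_modified
    return new


# ---------------------------------------------------------------------------
# Little's MCAR test
# ---------------------------------------------------------------------------

@dataclass
class MCARTestResult:
    statistic: float     # d^2, asymptotically chi-squared under MCAR
    dof: int             # sum_j p_j - p over missingness patterns
    p_value: float
    n_patterns: int
    n_obs: int = 0
    em_iterations: int = 0


def _em_mean_cov(Y: np.ndarray, tol: float = 1e-6, max_iter: int = 200):
    """ML mean/covariance of a multivariate normal with missing entries.

    Standard EM: rows are grouped by missingness pattern; the E-step fills
    conditional means and adds the conditional covariance of the missing
    block, the M-step recomputes the ML (1/n) moments.
    """
    n, p = Y.shape
    mask = np.isnan(Y)
    mu = np.nanmean(Y, axis=0)
    Y0 = np.where(mask, mu, Y)
    sigma = np.cov(Y0, rowvar=False, bias=True)
    sigma += np.eye(p) * 1e-10
    patterns: dict[tuple, list[int]] = {}
    for i, key in enumerate(map(tuple, mask)):
        patterns.setdefault(key, []).append(i)
    it = 0
    for it in range(1, max_iter + 1):
        S = np.zeros((p, p))
        total = np.zeros(p)
        for key, rows in patterns.items():
            miss = np.array(key)
            obs = ~miss
            Yg = Y[rows]
            m = len(rows)
            if miss.all():
                filled = np.tile(mu, (m, 1))
                cond_cov_full = sigma
            elif not miss.any():
                filled = Yg
                cond_cov_full = None
            else:
                Soo = sigma[np.ix_(obs, obs)]
                Smo = sigma[np.ix_(miss, obs)]
                Smm = sigma[np.ix_(miss, miss)]
                coef = np.linalg.solve(Soo, Smo.T).T
                filled = Yg.copy()
                filled[:, miss] = mu[miss] + (Yg[:, obs] - mu[obs]) @ coef.T
                cond_cov = Smm - coef @ Smo.T
                cond_cov_full = np.zeros((p, p))
                cond_cov_full[np.ix_(miss, miss)] = cond_cov
            total += filled.sum(axis=0)
            S += filled.T @ filled
            if cond_cov_full is not None:
                S += m * cond_cov_full
        mu_new = total / n
        sigma_new = S / n - np.outer(mu_new, mu_new)
        sigma_new += np.eye(p) * 1e-12
        shift = max(np.abs(mu_new - mu).max(),
                    np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if shift < tol:
            break
    return mu, sigma, it


def little_mcar_test(frame: EHRFrame, variables=None, tol: float = 1e-6,
                     max_iter: int = 200,
                     min_pattern_size: int = 1) -> MCARTestResult:
    """Little's chi-squared test of the MCAR hypothesis.

    Parameters
    ----------
    variables
        Numeric variables to test; defaults to all numeric-valued variables.
    tol, max_iter
        EM convergence tolerance on parameter change and iteration cap.
    min_pattern_size
        Patterns with fewer rows are dropped (with a warning) before the
        statistic is computed; the grand mean/covariance always use all rows.

    Raises
    ------
    DegenerateInputError
        If fewer than two distinct missingness patterns exist.
    """
    variables = list(variables) if variables is not None \
        else frame.numeric_var_names()
    Y, names = frame.numeric_matrix(variables)
    # rows missing everything carry no information about observed means
    keep = ~np.isnan(Y).all(axis=1)
    Y = Y[keep]
    n, p = Y.shape
    if n == 0 or p == 0:
        raise ValidationError("no data to test")
    mask = np.isnan(Y)
    pattern_rows: dict[tuple, list[int]] = {}
    for i, key in enumerate(map(tuple, mask)):
        pattern_rows.setdefault(key, []).append(i)
    if len(pattern_rows) < 2:
        raise DegenerateInputError(
            "Little's test needs at least two distinct missingness patterns")
    mu, sigma, it = _em_mean_cov(Y, tol=tol, max_iter=max_iter)
    d2 = 0.0
    dof = -p
    used = 0
    for key, rows in pattern_rows.items():
        if len(rows) < min_pattern_size:
            warnings.warn(
                f"dropping missingness pattern with {len(rows)} row(s)")
            continue
        obs = ~np.array(key)
        pj = int(obs.sum())
        if pj == 0:
            continue
        ybar = Y[np.ix_(rows, np.flatnonzero(obs))].mean(axis=0)
        diff = ybar - mu[obs]
        Soo = sigma[np.ix_(obs, obs)]
        try:
            solved = np.linalg.solve(Soo, diff)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular covariance for pattern {key}") from exc
        d2 += len(rows) * float(diff @ solved)
        dof += pj
        used += 1
    dof = max(int(dof), 0)
    p_value = float(stats.chi2.sf(d2, dof)) if dof > 0 else 1.0
    return MCARTestResult(statistic=float(d2), dof=dof, p_value=p_value,
                          n_patterns=used, n_obs=n, em_iterations=it)


# ---------------------------------------------------------------------------
# bias detection
# ---------------------------------------------------------------------------

@dataclass
class BiasReport:
    """Exploratory bias audit over sensitive groups.

    ``smd`` rows are (sensitive variable, group pair, numeric variable)
    standardized mean differences using the pooled standard deviation;
    ``categorical_differences`` holds raw and proportion value-count deltas;
    ``feature_importance`` is present when a prediction target was named.
    """

    correlations: pd.DataFrame
    smd: pd.DataFrame
    categorical_differences: pd.DataFrame
    feature_importance: pd.DataFrame | None = None


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return np.nan
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    return float(np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)))


def detect_bias(frame: EHRFrame, sensitive, target: str | None = None,
                seed: int = 0) -> BiasReport:
    """Screen for distributional differences across sensitive groups.

    Computes Pearson correlations between numeric variables (pairwise
    complete), standardized mean differences per sensitive-group pair and
    numeric variable, value-count differences for categorical variables, and
    (if ``target`` is given) a random-forest feature-importance ranking for
    predicting the target.
    """
    sensitive = list(sensitive)
    numeric = frame.numeric_var_names()
    M, names = frame.numeric_matrix(numeric)
    num_df = pd.DataFrame(M, columns=names, index=frame.obs_names)
    corr = num_df.corr(method="pearson")

    def _column(name):
        if name in frame.obs.columns:
            return np.asarray(frame.obs[name].to_numpy(), dtype=object)
        return frame.get_values(name)

    smd_rows, cat_rows = [], []
    cat_vars = [n for n in frame.var_names
                if frame.var.at[n, "kind"] in ("categorical", "boolean")
                and frame.var.at[n, "encoding_state"] == "raw"]
    for svar in sensitive:
        col = _column(svar)
        if all(isinstance(v, (int, float, np.floating)) and not pd.isna(v)
               for v in col):
            raise ValidationError(
                f"sensitive column {svar!r} must be categorical")
        groups = sorted({str(v) for v in col if not pd.isna(v)})
        labels = np.array([np.nan if pd.isna(v) else str(v) for v in col],
                          dtype=object)
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                m1 = labels == g1
                m2 = labels == g2
                for vname in names:
                    a = num_df.loc[m1, vname].dropna().to_numpy()
                    b = num_df.loc[m2, vname].dropna().to_numpy()
                    sd = _pooled_sd(a, b)
                    val = (a.mean() - b.mean()) / sd \
                        if sd and np.isfinite(sd) and sd > 0 else np.nan
                    smd_rows.append((svar, g1, g2, vname, val))
                for cname in cat_vars:
                    if cname == svar:
                        continue
                    cvals = frame.get_values(cname)
                    s1 = pd.Series(cvals[m1]).dropna().astype(str)
                    s2 = pd.Series(cvals[m2]).dropna().astype(str)
                    cats = sorted(set(s1) | set(s2))
                    for cat in cats:
                        c1, c2 = int((s1 == cat).sum()), int((s2 == cat).sum())
                        p1 = c1 / len(s1) if len(s1) else np.nan
                        p2 = c2 / len(s2) if len(s2) else np.nan
                        cat_rows.append((svar, g1, g2, cname, cat,
                                         c1 - c2, p1 - p2))
    smd = pd.DataFrame(smd_rows, columns=[
        "sensitive", "group1", "group2", "variable", "smd"])
    cat_diff = pd.DataFrame(cat_rows, columns=[
        "sensitive", "group1", "group2", "variable", "category",
        "count_difference", "proportion_difference"])

    importance = None
    if target is not None:
        from sklearn.ensemble import (RandomForestClassifier,
                                      RandomForestRegressor)
        y_raw = _column(target)
        ok = ~pd.isna(pd.Series(y_raw, dtype=object)).to_numpy()
        feats = [n for n in names if n != target]
        Xmat = num_df[feats].to_numpy()
        row_ok = ok & ~np.isnan(Xmat).any(axis=1)
        if row_ok.sum() < 10:
            raise ValidationError("too few complete rows for importance")
        y = y_raw[row_ok]
        if all(isinstance(v, (int, float, np.floating)) for v in y):
            model = RandomForestRegressor(n_estimators=100,
                                          random_state=seed)
            yfit = np.asarray(y, dtype=float)
        else:
            model = RandomForestClassifier(n_estimators=100,
                                           random_state=seed)
            yfit = np.asarray([str(v) for v in y])
        model.fit(Xmat[row_ok], yfit)
        importance = pd.DataFrame(
            {"variable": feats, "importance": model.feature_importances_}
        ).sort_values("importance", ascending=False).reset_index(drop=True)
    return BiasReport(corr, smd, cat_diff, importance)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def subsample(frame: EHRFrame, fraction: float, seed: int = 0) -> EHRFrame:
    """Draw ``floor(fraction * n_obs)`` observations without replacement."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    k = int(np.floor(fraction * frame.n_obs))
    pos = rng.choice(frame.n_obs, size=k, replace=False)
    return frame.subset_obs(np.sort(pos))


def balanced_sample(frame: EHRFrame, groupby: str, method: str = "under",
                    seed: int = 0) -> EHRFrame:
    """Equalize group sizes by random under- or oversampling.

    ``under`` keeps a random subset of each group at the minority size
    (without replacement); ``over`` resamples each group to the majority
    size (with replacement only for groups smaller than the majority).
    """
    if method not in ("under", "over"):
        raise ValueError("method must be 'under' or 'over'")
    if groupby in frame.obs.columns:
        labels = frame.obs[groupby].to_numpy()
    elif groupby in frame.var_names:
        labels = frame.get_values(groupby)
    else:
        raise KeyError(groupby)
    labels = np.array([np.nan if pd.isna(v) else str(v) for v in labels],
                      dtype=object)
    groups = sorted({v for v in labels if not pd.isna(v)})
    if len(groups) < 2:
        raise ValidationError("balanced_sample needs at least two groups")
    sizes = {g: int((labels == g).sum()) for g in groups}
    if min(sizes.values()) == 0:
        raise ValidationError("empty group")
    target = min(sizes.values()) if method == "under" else max(sizes.values())
    rng = np.random.default_rng(seed)
    pos = []
    for g in groups:
        members = np.flatnonzero(labels == g)
        if method == "under":
            pos.append(rng.choice(members, size=target, replace=False))
        else:
            if len(members) == target:
                pos.append(members)
            else:
                pos.append(rng.choice(members, size=target, replace=True))
    pos = np.concatenate(pos)
    new = frame.subset_obs(pos)
    # oversampling duplicates rows: make identifiers unique again
    if method == "over":
        new.obs.index = pd.Index(
            [f"{name}-{i}" for i, name in enumerate(new.obs.index)])
    return new
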