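"""Group feature ranking and survival statistics.

Feature ranking tests each group against the union of all other groups:
Welch t-tests for numeric variables, likelihood-ratio (g-) tests for
categorical variables, with Benjamini-Hochberg adjustment across features
within each group.  Survival estimation (Kaplan-Meier, log-rank, Cox) is
delegated to lifelines; the concordance index gets a bootstrap percentile
confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EHRFrame
from .errors import ValidationError

__all__ = [
    "RankResult", "KMCurve", "LogRankResult", "CoxResult",
    "rank_features_groups", "g_test", "benjamini_hochberg",
    "kaplan_meier", "logrank_test", "cox_ph", "concordance_ci",
    "fit_glm", "compare_glm",
]


# ---------------------------------------------------------------------------
# feature ranking
# ---------------------------------------------------------------------------

@dataclass
class RankResult:
    """Per-group feature ranking table.

    ``table`` columns: group, variable, test, statistic, p_value,
    p_adjusted, summary (mean+/-sd for numeric, category proportions for
    categorical); rows sorted within each group by adjusted p then by
    descending absolute statistic.
    """

    table: pd.DataFrame

    def top(self, group: str, n: int = 10) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        return sub.head(n).reset_index(drop=True)


def g_test(observed: np.ndarray):
    """Likelihood-ratio test of independence: G = 2 sum O ln(O/E).

    Expected counts come from the table margins; observed zeros contribute
    nothing; categories with zero expected count are dropped.  Returns
    (G, dof, p).
    """
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2:
        raise ValidationError("g_test expects a 2-D contingency table")
    keep_rows = O.sum(axis=1) > 0
    keep_cols = O.sum(axis=0) > 0
    O = O[np.ix_(keep_rows, keep_cols)]
    if O.shape[0] < 2 or O.shape[1] < 2:
        return 0.0, 0, 1.0
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    G = 2.0 * float(terms.sum())
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    return G, dof, float(stats.chi2.sf(G, dof))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up false-discovery-rate adjustment (monotone, idempotent)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def rank_features_groups(frame: EHRFrame, groupby: str,
                         groups=None) -> RankResult:
    """Rank features by group-vs-rest two-sided tests.

    Numeric variables use Welch t-tests; raw categorical/boolean variables
    use g-tests on the group-vs-rest x category contingency table.
    Benjamini-Hochberg adjustment is applied across features within each
    group.  Zero-variance numeric comparisons get p = 1 and a flag.
    """
    if groupby in frame.obs.columns:
        raw = frame.obs[groupby].to_numpy()
    elif groupby in frame.var_names:
        raw = frame.get_values(groupby)
    else:
        raise KeyError(groupby)
    labels = np.array([np.nan if pd.isna(v) else str(v) for v in raw],
                      dtype=object)
    levels = sorted({v for v in labels if not pd.isna(v)})
    if len(levels) < 2:
        raise ValidationError("rank_features_groups needs >= 2 groups")
    if groups is None:
        groups = levels
    numeric = frame.numeric_var_names()
    cat_vars = [n for n in frame.var_names
                if frame.var.at[n, "kind"] in ("categorical", "boolean")
                and frame.var.at[n, "encoding_state"] == "raw"]
    M, num_names = frame.numeric_matrix(numeric)
    rows = []
    for g in groups:
        in_g = labels == g
        in_rest = np.array([(not pd.isna(v)) and v != g for v in labels])
        for j, name in enumerate(num_names):
            a = M[in_g, j]
            b = M[in_rest, j]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a) < 2 or len(b) < 2:
                continue
            flagged = False
            if np.var(a) == 0 and np.var(b) == 0:
                if np.allclose(a.mean(), b.mean()):
                    t, p = 0.0, 1.0
                else:
                    t, p = np.inf, 0.0
                flagged = True
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            summary = f"{a.mean():.4g}+/-{a.std(ddof=1):.4g}"
            rows.append((g, name, "t-test", float(t), float(p), summary,
                         flagged))
        for name in cat_vars:
            if name == groupby:
                continue
            vals = frame.get_values(name)
            s = pd.Series([np.nan if pd.isna(v) else str(v) for v in vals],
                          dtype=object)
            cats = sorted(s.dropna().unique())
            if len(cats) < 2:
                continue
            table = np.array([
                [(s[in_g] == c).sum() for c in cats],
                [(s[in_rest] == c).sum() for c in cats],
            ], dtype=float)
            G, dof, p = g_test(table)
            with np.errstate(invalid="ignore"):
                props = table[0] / max(table[0].sum(), 1)
            summary = ";".join(f"{c}:{pr:.3f}" for c, pr in zip(cats, props))
            rows.append((g, name, "g-test", float(G), float(p), summary,
                         False))
    df = pd.DataFrame(rows, columns=["group", "variable", "test",
                                     "statistic", "p_value", "summary",
                                     "zero_variance"])
    adj = np.empty(len(df))
    for g in groups:
        m = (df["group"] == g).to_numpy()
        adj[m] = benjamini_hochberg(df.loc[m, "p_value"].to_numpy())
    df["p_adjusted"] = adj
    df = df.sort_values(
        ["group", "p_adjusted", "statistic"],
        key=lambda s: -s.abs() if s.name == "statistic" else s,
    ).reset_index(drop=True)
    df["rank"] = df.groupby("group").cumcount()
    return RankResult(df[["group", "variable", "test", "statistic",
                          "p_value", "p_adjusted", "summary",
                          "zero_variance", "rank"]])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood-based 95% band.

    The confidence band is computed on the log(-log) scale (exponential
    Greenwood), keeping the bounds inside [0, 1].
    """

    group: str
    times: np.ndarray           # ordered distinct event times
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray        # S(t) just after each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
        return s


@dataclass
class LogRankResult:
    """Log-rank comparison of group hazard functions.

    Tests H0: h1(t) = h2(t) against Ha: h1(t) = c * h2(t) with c != 1 using
    log-rank weights; chi-squared with (n groups - 1) degrees of freedom.
    """

    statistic: float
    dof: int
    p_value: float


@dataclass
class CoxResult:
    summary: pd.DataFrame        # coef, se, ci lower/upper, p per covariate
    log_likelihood: float
    partial_hazards: np.ndarray
    model: object = field(repr=False, default=None)

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["coef"]


def _check_survival_inputs(durations, events):
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events).astype(bool)
    if (durations < 0).any():
        raise ValueError("durations must be non-negative")
    if len(durations) != len(events):
        raise ValidationError("durations and events must align")
    return durations, events


def kaplan_meier(durations, events, groupby=None) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit estimate per group.

    Returns a map group label -> :class:`KMCurve` (single key ``"all"``
    without ``groupby``).
    """
    from lifelines import KaplanMeierFitter

    durations, events = _check_survival_inputs(durations, events)
    if groupby is None:
        groupby = np.array(["all"] * len(durations), dtype=object)
    groupby = np.asarray(groupby, dtype=object)
    out = {}
    for g in sorted({str(v) for v in groupby}):
        m = np.array([str(v) == g for v in groupby])
        kmf = KaplanMeierFitter()
        kmf.fit(durations[m], events[m])
        tbl = kmf.event_table[kmf.event_table["observed"] > 0]
        times = tbl.index.to_numpy(dtype=float)
        surv = np.array([float(kmf.survival_function_at_times(t).iloc[0])
                         for t in times])
        ci = kmf.confidence_interval_survival_function_
        lo = np.array([float(ci.iloc[ci.index.get_indexer([t])[0], 0])
                       for t in times]) if len(times) else np.array([])
        hi = np.array([float(ci.iloc[ci.index.get_indexer([t])[0], 1])
                       for t in times]) if len(times) else np.array([])
        out[g] = KMCurve(group=g, times=times,
                         at_risk=tbl["at_risk"].to_numpy(),
                         events=tbl["observed"].to_numpy(),
                         survival=surv, ci_lower=lo, ci_upper=hi)
    return out


def logrank_test(durations, events, groups) -> LogRankResult:
    """Multivariate log-rank test across >= 2 groups."""
    from lifelines.statistics import multivariate_logrank_test

    durations, events = _check_survival_inputs(durations, events)
    groups = np.asarray([str(g) for g in np.asarray(groups, dtype=object)])
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValidationError("logrank_test needs >= 2 groups")
    for g in levels:
        if (groups == g).sum() == 0:
            raise ValidationError(f"group {g!r} is empty")
    res = multivariate_logrank_test(durations, groups, events)
    return LogRankResult(statistic=float(res.test_statistic),
                         dof=len(levels) - 1,
                         p_value=float(res.p_value))


def cox_ph(frame: EHRFrame, duration_col: str, event_col: str,
           covariates) -> CoxResult:
    """Cox proportional-hazards partial-likelihood fit.

    ``duration_col``/``event_col`` and covariates may live in the obs table
    or the data matrix; model columns must be complete.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = list(covariates)

    def _col(name):
        if name in frame.obs.columns:
            return pd.to_numeric(pd.Series(frame.obs[name].to_numpy()),
                                 errors="coerce").to_numpy(dtype=float)
        if name in frame.var_names:
            return np.array([np.nan if pd.isna(v) else float(v)
                             for v in frame.get_values(name)])
        raise KeyError(name)

    data = {duration_col: _col(duration_col),
            event_col: _col(event_col)}
    for c in covariates:
        data[c] = _col(c)
    df = pd.DataFrame(data)
    if df.isna().any().any():
        raise ValidationError("model columns contain missing values; "
                              "impute first")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValidationError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise np.linalg.LinAlgError(
            f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "ci_lower": s["coef lower 95%"],
        "ci_upper": s["coef upper 95%"],
        "p_value": s["p"],
        "hazard_ratio": np.exp(s["coef"]),
    })
    ph = cph.predict_partial_hazard(df).to_numpy(dtype=float)
    return CoxResult(summary=summary,
                     log_likelihood=float(cph.log_likelihood_),
                     partial_hazards=ph, model=cph)


def concordance_ci(partial_hazards, durations, events, n_boot: int = 1000,
                   seed: int = 0):
    """Concordance index with bootstrap percentile 95% CI.

    Higher hazard should fail earlier.  The CI resamples (hazard, duration,
    event) triples with replacement ``n_boot`` times and takes the 2.5% and
    97.5% percentiles of the resampled C-indices.
    """
    from lifelines.utils import concordance_index

    hz = np.asarray(partial_hazards, dtype=float)
    durations, events = _check_survival_inputs(durations, events)
    if not events.any():
        raise ValidationError("no comparable pairs (no observed events)")
    c = float(concordance_index(durations, -hz, events))
    rng = np.random.default_rng(seed)
    n = len(hz)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if not events[idx].any():
            boot[b] = np.nan
            continue
        boot[b] = concordance_index(durations[idx], -hz[idx], events[idx])
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return c, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# generalized linear models
# ---------------------------------------------------------------------------

_FAMILIES = {
    "gaussian": "Gaussian", "binomial": "Binomial", "poisson": "Poisson",
    "gamma": "Gamma", "inverse_gaussian": "InverseGaussian",
}


def _frame_dataframe(frame: EHRFrame) -> pd.DataFrame:
    df = frame.obs.copy()
    for name in frame.var_names:
        df[name] = frame.get_values(name)
    return df


def fit_glm(frame: EHRFrame, formula: str, family: str = "gaussian"):
    """Maximum-likelihood GLM fit from a formula over obs + matrix columns.

    Returns the fitted statsmodels results object (coefficients,
    log-likelihood, deviance).  ``family='gaussian'`` with the identity link
    reproduces OLS.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; "
                         f"choose from {sorted(_FAMILIES)}")
    fam = getattr(sm.families, _FAMILIES[family])()
    df = _frame_dataframe(frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smf.glm(formula, data=df, family=fam).fit()


def compare_glm(larger, smaller) -> float:
    """Likelihood-ratio p-value for a nested GLM comparison.

    ``larger`` must nest ``smaller`` on the same data.  The statistic is
    2 * (llf_larger - llf_smaller) on dof = parameter-count difference;
    dof = 0 is degenerate and returns p = 1.
    """
    small_terms = set(smaller.params.index)
    large_terms = set(larger.params.index)
    if not small_terms <= large_terms:
        raise ValidationError("models are not nested")
    if larger.nobs != smaller.nobs:
        raise ValidationError("models were fit on different data")
    dof = int(larger.df_model - smaller.df_model)
    if dof <= 0:
        return 1.0
    stat = 2.0 * (larger.llf - smaller.llf)
    return float(stats.chi2.sf(max(stat, 0.0), dof))
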