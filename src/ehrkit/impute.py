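"""Missing-value imputation: explicit, simple statistics, k-nearest
neighbors, and iterative random forests (MissForest).

Every imputer returns a new frame plus an :class:`ImputationReport`; no
originally observed entry is ever altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EHRFrame
from .errors import ValidationError

__all__ = [
    "ImputationReport",
    "impute_explicit", "impute_simple", "impute_knn", "impute_missforest",
]


@dataclass
class ImputationReport:
    method: str
    parameters: dict
    imputed_counts: dict[str, int]
    iterations: int = 0
    convergence_trace: list[float] = field(default_factory=list)

    @property
    def total_imputed(self) -> int:
        return sum(self.imputed_counts.values())


def _target_variables(frame: EHRFrame, variables) -> list[str]:
    if variables is None:
        return list(frame.var_names)
    variables = list(variables)
    for name in variables:
        if name not in frame.var_names:
            raise KeyError(name)
    return variables


def impute_explicit(frame: EHRFrame, value, variables=None):
    """Replace missing entries with a designated value.

    ``value`` is a scalar applied to every targeted variable or a map
    variable -> replacement.  Replacements for numeric variables must be
    numeric; for raw categorical variables they must be strings.
    """
    variables = _target_variables(frame, variables)
    if isinstance(value, dict):
        mapping = dict(value)
        missing_keys = set(mapping) - set(variables)
        if missing_keys:
            raise KeyError(sorted(missing_keys)[0])
    else:
        mapping = {name: value for name in variables}
    new = frame.copy()
    counts = {}
    for name, repl in mapping.items():
        col = new.get_values(name)
        mask = pd.isna(pd.Series(col, dtype=object)).to_numpy()
        numeric_col = all(isinstance(v, (int, float, np.floating))
                          for v, m in zip(col, mask) if not m)
        if numeric_col and not isinstance(repl, (int, float, np.floating)):
            raise ValidationError(
                f"replacement for numeric variable {name!r} must be numeric")
        col[mask] = float(repl) if isinstance(
            repl, (int, float, np.floating)) else str(repl)
        new.set_values(name, col)
        counts[name] = int(mask.sum())
    new.compact()
    return new, ImputationReport("explicit", {"value": value}, counts)


def impute_simple(frame: EHRFrame, strategy: str = "mean", variables=None):
    """Impute with a per-variable statistic: mean, median or most_frequent.

    ``mean``/``median`` require numeric variables; ``most_frequent`` also
    handles raw categoricals (modal category, ties broken lexicographically).
    """
    if strategy not in ("mean", "median", "most_frequent"):
        raise ValueError(f"unknown strategy {strategy!r}")
    variables = _target_variables(frame, variables)
    new = frame.copy()
    counts = {}
    for name in variables:
        col = new.get_values(name)
        ser = pd.Series(col, dtype=object)
        mask = ser.isna().to_numpy()
        if not mask.any():
            counts[name] = 0
            continue
        obs = ser[~mask]
        numeric_col = all(isinstance(v, (int, float, np.floating))
                          for v in obs)
        if strategy in ("mean", "median") and not numeric_col:
            raise ValidationError(
                f"{strategy} imputation requires numeric variable, "
                f"got {name!r}")
        if strategy == "mean":
            repl = float(np.mean(obs.astype(float)))
        elif strategy == "median":
            repl = float(np.median(obs.astype(float)))
        else:
            vc = obs.value_counts()
            top = vc[vc == vc.max()].index
            repl = sorted(top)[0]
        col[mask] = repl
        new.set_values(name, col)
        counts[name] = int(mask.sum())
    new.compact()
    return new, ImputationReport("simple", {"strategy": strategy}, counts)


def impute_knn(frame: EHRFrame, k: int = 20, distance: str = "nan_euclidean",
               variables=None, weights: str = "uniform"):
    """k-nearest-neighbor imputation on the numeric matrix.

    Distances between incomplete rows are Euclidean over jointly observed
    coordinates rescaled by sqrt(p / p_observed); each missing entry becomes
    the (optionally distance-weighted) average of that variable over the k
    nearest rows with an observed value.  Categorical variables must be
    encoded first.
    """
    if k >= frame.n_obs:
        raise ValueError("k must be smaller than the number of observations")
    from sklearn.impute import KNNImputer

    variables = [v for v in _target_variables(frame, variables)]
    numeric = frame.numeric_var_names()
    if set(variables) - set(numeric):
        raise ValidationError("impute_knn requires numeric (encoded) "
                              "variables")
    M, names = frame.numeric_matrix(numeric)
    pre_missing = np.isnan(M)
    imputer = KNNImputer(n_neighbors=k, metric=distance, weights=weights)
    filled = imputer.fit_transform(M)
    if filled.shape[1] != M.shape[1]:  # all-missing columns are dropped
        raise ValidationError("a variable has no observed values")
    new = frame.copy()
    out = M.copy()
    target_idx = [names.index(v) for v in variables if v in names]
    for j in target_idx:
        out[:, j] = filled[:, j]
    new.set_numeric_matrix(out, names)
    counts = {names[j]: int(pre_missing[:, j].sum()) for j in target_idx}
    return new, ImputationReport("knn", {"k": k, "distance": distance},
                                 counts)


def impute_missforest(frame: EHRFrame, max_iter: int = 10,
                      n_trees: int = 100, seed: int = 0, variables=None):
    """Iterative random-forest (MissForest) imputation.

    Starting from a mean/mode fill, variables are revisited in order of
    increasing missingness; each is regressed on all others with a random
    forest fitted on its originally observed rows and predicted on its
    originally missing rows.  Iteration stops when the normalized sum of
    squared changes between successive imputations first increases, or after
    ``max_iter`` rounds.  Label-encoded categoricals (consecutive integer
    codes) are modelled with classification forests.
    """
    from sklearn.ensemble import (RandomForestClassifier,
                                  RandomForestRegressor)

    numeric = frame.numeric_var_names()
    if len(numeric) < 2:
        raise ValidationError("MissForest needs at least two variables")
    variables = _target_variables(frame, variables)
    variables = [v for v in variables if v in numeric]
    M, names = frame.numeric_matrix(numeric)
    miss = np.isnan(M)
    counts = {names[j]: int(miss[:, j].sum()) for j in range(len(names))
              if names[j] in variables}
    if not miss.any():
        return frame.copy(), ImputationReport(
            "missforest", {"max_iter": max_iter, "n_trees": n_trees,
                           "seed": seed}, counts, iterations=0)

    categorical = np.array([
        frame.var.at[n, "encoding_state"] == "label" for n in names])
    # initialization: mean for numeric, mode for label-encoded categoricals
    cur = M.copy()
    for j in range(cur.shape[1]):
        if not miss[:, j].any():
            continue
        obs = cur[~miss[:, j], j]
        if obs.size == 0:
            raise ValidationError(f"variable {names[j]!r} fully missing")
        if categorical[j]:
            vals, cnt = np.unique(obs, return_counts=True)
            cur[miss[:, j], j] = vals[np.argmax(cnt)]
        else:
            cur[miss[:, j], j] = obs.mean()

    order = np.argsort(miss.sum(axis=0))
    order = [j for j in order if miss[:, j].any()
             and names[j] in variables]
    rng = np.random.default_rng(seed)
    prev = cur.copy()
    trace: list[float] = []
    best = cur.copy()
    for iteration in range(1, max_iter + 1):
        for j in order:
            obs_rows = ~miss[:, j]
            others = [c for c in range(cur.shape[1]) if c != j]
            Xfit = cur[np.ix_(obs_rows, others)]
            yfit = cur[obs_rows, j]
            Xpred = cur[np.ix_(miss[:, j], others)]
            rs = int(rng.integers(0, 2**31 - 1))
            if categorical[j]:
                model = RandomForestClassifier(n_estimators=n_trees,
                                               random_state=rs, n_jobs=1)
                model.fit(Xfit, yfit.astype(int))
                cur[miss[:, j], j] = model.predict(Xpred).astype(float)
            else:
                model = RandomForestRegressor(n_estimators=n_trees,
                                              random_state=rs, n_jobs=1)
                model.fit(Xfit, yfit)
                cur[miss[:, j], j] = model.predict(Xpred)
        denom = float(np.sum(cur[miss] ** 2)) or 1.0
        delta = float(np.sum((cur[miss] - prev[miss]) ** 2)) / denom
        trace.append(delta)
        if len(trace) >= 2 and delta > trace[-2]:
            cur = best  # last decrease wins (original stopping convention)
            break
        best = cur.copy()
        prev = cur.copy()
    new = frame.copy()
    out, _ = new.numeric_matrix(names)
    for j, name in enumerate(names):
        if name in variables:
            out[:, j] = cur[:, j]
        else:
            out[:, j] = np.where(miss[:, j], np.nan, out[:, j])
    new.set_numeric_matrix(out, names)
    return new, ImputationReport(
        "missforest",
        {"max_iter": max_iter, "n_trees": n_trees, "seed": seed},
        counts, iterations=len(trace), convergence_trace=trace)
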