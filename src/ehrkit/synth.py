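"""Synthetic EHR cohorts with controlled structure.

The generators cover the features the analysis modules need to be testable
without external data: mixed-type clinical features with group structure,
repeated per-patient measurements, the three missing-data mechanisms
(MCAR / MAR / MNAR) with explicit parameterizations, survival outcomes with
group hazard differences, and linear structural causal models with a known
total effect.

Every generator is a pure function of (configuration, seed).

The MAR injector reproduces the standard construction used in missing-data
benchmarking: the driver variable is standardized, mapped through
``logistic(scale * z + offset)`` and the target entry is removed by a
Bernoulli draw of that probability.  The defaults ``scale=1.2`` and
``offset=-0.6`` give an overall missingness rate around one third with a
strong observable dependence on the driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causal import CausalGraph
from .core import EHRFrame
from .errors import ValidationError

__all__ = [
    "NumericFeature", "CategoricalFeature", "CohortConfig", "SCMSpec",
    "make_cohort", "inject_mcar", "inject_mar", "inject_mnar",
    "simulate_survival_cohort", "simulate_scm", "logistic",
]


def logistic(x):
    """1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class NumericFeature:
    name: str
    mean: float = 0.0
    sd: float = 1.0
    group_shifts: dict[str, float] = field(default_factory=dict)


@dataclass
class CategoricalFeature:
    name: str
    levels: list[str]
    probabilities: list[float]

    def __post_init__(self):
        if len(self.levels) != len(self.probabilities):
            raise ValidationError("levels and probabilities must align")
        if abs(sum(self.probabilities) - 1.0) > 1e-8:
            raise ValidationError("probabilities must sum to 1")


@dataclass
class CohortConfig:
    """Specification of a synthetic patient-visit cohort."""

    n_patients: int = 1000
    numeric_features: list[NumericFeature] = field(default_factory=list)
    categorical_features: list[CategoricalFeature] = field(
        default_factory=list)
    group: CategoricalFeature | None = None
    correlation: float = 0.0   # shared-factor correlation between numerics
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not (0 <= self.correlation < 1):
            raise ValidationError("correlation must lie in [0, 1)")


def make_cohort(config: CohortConfig) -> EHRFrame:
    """Sample a cohort frame from the configuration.

    Numeric features are Gaussian with optional per-group mean shifts; an
    equicorrelation ``config.correlation`` between numeric features is
    induced by a shared latent factor.  The group variable (if any) is
    stored in the obs table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    obs = pd.DataFrame(index=pd.Index([f"p{i}" for i in range(n)]))
    group_labels = None
    if config.group is not None:
        group_labels = rng.choice(config.group.levels, size=n,
                                  p=config.group.probabilities)
        obs[config.group.name] = group_labels
    cols, names, kinds = [], [], []
    shared = rng.standard_normal(n)
    r = config.correlation
    for f in config.numeric_features:
        eps = rng.standard_normal(n)
        z = np.sqrt(r) * shared + np.sqrt(1 - r) * eps
        vals = f.mean + f.sd * z
        if f.group_shifts and group_labels is not None:
            shift = np.array([f.group_shifts.get(str(g), 0.0)
                              for g in group_labels])
            vals = vals + shift
        cols.append(np.asarray(vals, dtype=object))
        names.append(f.name)
        kinds.append("numeric")
    for f in config.categorical_features:
        vals = rng.choice(f.levels, size=n, p=f.probabilities)
        cols.append(np.array([str(v) for v in vals], dtype=object))
        names.append(f.name)
        kinds.append("categorical")
    if not cols:
        raise ValidationError("cohort config declares no features")
    X = np.column_stack(cols)
    var = pd.DataFrame({"kind": kinds, "encoding_state": "raw"},
                       index=pd.Index(names))
    frame = EHRFrame(X, obs, var)
    for f in config.categorical_features:
        frame.set_categories(f.name, sorted(set(f.levels)))
    frame.compact()
    return frame


def inject_mcar(frame: EHRFrame, variable: str, rate: float,
                seed: int = 0) -> EHRFrame:
    """Set each entry of ``variable`` missing independently with
    probability ``rate`` (missing completely at random)."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0, 1]")
    new = frame.copy()
    col = new.get_values(variable)
    rng = np.random.default_rng(seed)
    mask = rng.random(new.n_obs) < rate
    col[mask] = np.nan
    new.set_values(variable, col)
    return new


def inject_mar(frame: EHRFrame, target: str, driver: str,
               scale: float = 1.2, offset: float = -0.6,
               seed: int = 0) -> EHRFrame:
    """Missing-at-random injection driven by an observed variable.

    The driver is standardized to mean 0 / sd 1 (population convention);
    each target entry is removed by a Bernoulli draw with probability
    ``logistic(scale * z_driver + offset)``.  With the defaults (1.2, -0.6)
    higher driver values make the target much more likely to be missing.
    """
    new = frame.copy()
    d = np.array([np.nan if pd.isna(v) else float(v)
                  for v in new.get_values(driver)])
    if np.isnan(d).any():
        raise ValidationError("driver variable must be complete")
    z = (d - d.mean()) / d.std(ddof=0)
    prob = logistic(scale * z + offset)
    rng = np.random.default_rng(seed)
    mask = rng.random(new.n_obs) < prob
    col = new.get_values(target)
    col[mask] = np.nan
    new.set_values(target, col)
    return new


def inject_mnar(frame: EHRFrame, target: str, scale: float = 1.2,
                offset: float = -0.6, seed: int = 0) -> EHRFrame:
    """Missing-not-at-random injection: the removal probability is the
    logistic of the standardized value being removed itself."""
    new = frame.copy()
    t = np.array([np.nan if pd.isna(v) else float(v)
                  for v in new.get_values(target)])
    obs = ~np.isnan(t)
    z = np.zeros_like(t)
    z[obs] = (t[obs] - t[obs].mean()) / t[obs].std(ddof=0)
    prob = logistic(scale * z + offset)
    rng = np.random.default_rng(seed)
    mask = obs & (rng.random(new.n_obs) < prob)
    col = new.get_values(target)
    col[mask] = np.nan
    new.set_values(target, col)
    return new


def simulate_survival_cohort(n_per_group: int, group_hazards: dict,
                             censor_rate: float = 0.2,
                             seed: int = 0) -> EHRFrame:
    """Exponential event times per group with independent censoring.

    ``group_hazards`` maps group label -> hazard (> 0).  Censoring times are
    exponential with rate ``censor_rate * mean hazard``; ``censor_rate=0``
    observes every event.  Columns ``duration`` and ``event`` are written to
    the data matrix, the group label to the obs table.
    """
    if censor_rate < 0 or censor_rate >= 1:
        raise ValueError("censor rate must lie in [0, 1)")
    for g, h in group_hazards.items():
        if h <= 0:
            raise ValueError(f"hazard for group {g!r} must be positive")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    mean_h = float(np.mean(list(group_hazards.values())))
    for g in sorted(group_hazards):
        h = group_hazards[g]
        t_event = rng.exponential(1.0 / h, size=n_per_group)
        if censor_rate > 0:
            t_cens = rng.exponential(1.0 / (censor_rate * mean_h),
                                     size=n_per_group)
        else:
            t_cens = np.full(n_per_group, np.inf)
        duration = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(float)
        rows.append(np.column_stack([duration, event]))
        labels.extend([str(g)] * n_per_group)
    X = np.vstack(rows)
    obs = pd.DataFrame({"group": labels},
                       index=pd.Index([f"s{i}" for i in range(len(labels))]))
    var = pd.DataFrame({"kind": "numeric", "encoding_state": "raw"},
                       index=pd.Index(["duration", "event"]))
    return EHRFrame(X.astype(np.float64), obs, var)


@dataclass
class SCMSpec:
    """Linear-Gaussian structural causal model.

    Each node is a linear function of its parents plus Gaussian noise;
    ``coefficients`` maps (parent, child) -> weight.  The treatment node can
    be binarized by thresholding its latent value at
    ``treatment_threshold`` (at least one administration vs none), in which
    case downstream equations consume the binary indicator.
    """

    graph: CausalGraph
    coefficients: dict[tuple[str, str], float]
    noise_scales: dict[str, float] = field(default_factory=dict)
    treatment: str | None = None
    outcome: str | None = None
    binarize_treatment: bool = False
    treatment_threshold: float = 0.0

    def __post_init__(self):
        for edge in self.graph.edges:
            if tuple(edge) not in self.coefficients:
                raise ValidationError(f"no coefficient for edge {edge}")

    def true_total_effect(self) -> float:
        """Sum over directed treatment->outcome paths of the products of
        path coefficients."""
        if self.treatment is None or self.outcome is None:
            raise ValidationError("treatment and outcome must be set")

        def paths_from(node):
            if node == self.outcome:
                return 1.0
            total = 0.0
            for child in self.graph.children(node):
                total += self.coefficients[(node, child)] * paths_from(child)
            return total

        return float(paths_from(self.treatment))


def simulate_scm(spec: SCMSpec, n: int, seed: int = 0) -> EHRFrame:
    """Ancestral sampling from a linear-Gaussian SCM.

    Nodes are sampled in topological order; the recorded true total effect
    of treatment on outcome is stored in ``uns['ehrkit']['scm']`` for test
    harnesses.
    """
    rng = np.random.default_rng(seed)
    order = spec.graph.topological_order()
    values: dict[str, np.ndarray] = {}
    for node in order:
        scale = float(spec.noise_scales.get(node, 1.0))
        v = rng.standard_normal(n) * scale if scale > 0 else np.zeros(n)
        for parent in sorted(spec.graph.parents(node)):
            v = v + spec.coefficients[(parent, node)] * values[parent]
        if node == spec.treatment and spec.binarize_treatment:
            v = (v > spec.treatment_threshold).astype(float)
        values[node] = v
    X = np.column_stack([values[node] for node in order])
    obs = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(n)]))
    var = pd.DataFrame({"kind": "numeric", "encoding_state": "raw"},
                       index=pd.Index(order))
    frame = EHRFrame(X.astype(np.float64), obs, var)
    if spec.treatment is not None and spec.outcome is not None:
        frame.uns["ehrkit"]["scm"] = {
            "treatment": spec.treatment, "outcome": spec.outcome,
            "true_effect": spec.true_total_effect(),
        }
    return frame
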