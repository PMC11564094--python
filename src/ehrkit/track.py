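"""Provenance log of cohort filtering.

A :class:`CohortLog` records every filtering step applied to a frame: the
free-text reason, population counts before and after, and distribution
snapshots (category counts, or mean/sd/quartiles for numeric columns) of a
set of tracked variables.  Snapshots store distributions rather than row
identifiers, keeping logs small and free of direct identifiers.  The log
renders as a tableone-style summary table per step and as node/edge data
for a consort-style flow diagram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EHRFrame
from .errors import ValidationError

__all__ = ["CohortLog", "tracker_start", "tracker_record",
           "tracker_summary", "tracker_flow"]


@dataclass
class CohortLog:
    tracked_columns: list[str]
    steps: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"tracked_columns": self.tracked_columns,
                           "steps": self.steps}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortLog":
        payload = json.loads(text)
        return cls(payload["tracked_columns"], payload["steps"])


def _column_values(frame: EHRFrame, name: str) -> np.ndarray:
    if name in frame.obs.columns:
        return np.asarray(frame.obs[name].to_numpy(), dtype=object)
    if name in frame.var_names:
        return frame.get_values(name)
    raise KeyError(name)


def _snapshot(frame: EHRFrame, columns) -> dict:
    snap = {}
    for name in columns:
        vals = _column_values(frame, name)
        ser = pd.Series(vals, dtype=object).dropna()
        numeric = len(ser) > 0 and all(
            isinstance(v, (int, float, np.floating)) for v in ser)
        if numeric:
            arr = ser.astype(float).to_numpy()
            q1, med, q3 = (np.percentile(arr, [25, 50, 75])
                           if arr.size else (np.nan,) * 3)
            snap[name] = {"type": "numeric",
                          "mean": float(arr.mean()),
                          "sd": float(arr.std(ddof=1)) if arr.size > 1
                          else 0.0,
                          "q1": float(q1), "median": float(med),
                          "q3": float(q3), "n": int(arr.size)}
        else:
            counts = ser.astype(str).value_counts().sort_index()
            snap[name] = {"type": "categorical",
                          "counts": {k: int(v) for k, v in counts.items()},
                          "n_missing": int(len(vals) - len(ser))}
    return snap


def tracker_start(frame: EHRFrame, columns=()) -> CohortLog:
    """Initialize a cohort log with a step-0 snapshot of the full cohort."""
    columns = list(columns)
    for name in columns:
        _column_values(frame, name)  # raises KeyError for unknown columns
    log = CohortLog(tracked_columns=columns)
    log.steps.append({"reason": "initial cohort",
                      "n_before": int(frame.n_obs),
                      "n_after": int(frame.n_obs),
                      "snapshot": _snapshot(frame, columns)})
    return log


def tracker_record(log: CohortLog, frame: EHRFrame, reason: str) -> CohortLog:
    """Append a filtering step; the cohort must not have grown."""
    if not log.steps:
        raise ValidationError("log has no initial step")
    prev = log.steps[-1]["n_after"]
    if frame.n_obs > prev:
        raise ValidationError(
            "observation count grew; cohort tracking records filtering only")
    log.steps.append({"reason": str(reason),
                      "n_before": int(prev),
                      "n_after": int(frame.n_obs),
                      "snapshot": _snapshot(frame, log.tracked_columns)})
    return log


def tracker_summary(log: CohortLog, step: int = -1) -> pd.DataFrame:
    """Tableone-style summary of the tracked columns at one step.

    Categorical rows show ``count (percent%)``; numeric rows show
    ``mean +/- sd``.
    """
    try:
        record = log.steps[step]
    except IndexError:
        raise IndexError(f"log has {len(log.steps)} steps") from None
    rows = []
    n = record["n_after"]
    rows.append(("n", "", str(n)))
    for name, snap in record["snapshot"].items():
        if snap["type"] == "numeric":
            rows.append((name, "mean (sd)",
                         f"{snap['mean']:.2f} ({snap['sd']:.2f})"))
        else:
            for cat, count in snap["counts"].items():
                pct = 100.0 * count / n if n else 0.0
                rows.append((name, cat, f"{count} ({pct:.1f}%)"))
    return pd.DataFrame(rows, columns=["variable", "level", "value"])


def tracker_flow(log: CohortLog) -> dict:
    """Node/edge data for a consort-style flow diagram.

    One node per step (with its population count), one edge per transition
    (with the reason and the excluded count).
    """
    nodes = [{"step": i, "reason": s["reason"], "n": s["n_after"]}
             for i, s in enumerate(log.steps)]
    edges = [{"source": i - 1, "target": i,
              "reason": log.steps[i]["reason"],
              "excluded": log.steps[i]["n_before"] - log.steps[i]["n_after"]}
             for i in range(1, len(log.steps))]
    return {"nodes": nodes, "edges": edges}
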