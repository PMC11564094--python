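"""Lossless numeric encoding of categorical and boolean variables.

Two methods are provided: one-hot (one indicator column per category) and
label (consecutive integer codes).  The original values are kept in the
frame's unstructured store so :func:`decode` restores them exactly,
including missing entries, which one-hot encoding propagates as a full row
of missing markers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EHRFrame
from .errors import StateError, ValidationError

__all__ = ["encode", "decode"]

METHODS = ("one_hot", "label")


def _encoding_store(frame: EHRFrame) -> dict:
    return frame.uns["ehrkit"].setdefault("encoding", {})


def encode(frame: EHRFrame, spec: dict[str, str] | None = None,
           default_method: str = "one_hot") -> EHRFrame:
    """Encode categorical/boolean variables to numeric columns.

    Parameters
    ----------
    spec
        Map variable -> method (``one_hot`` or ``label``).  When omitted,
        every raw categorical/boolean variable is encoded with
        ``default_method``.
    default_method
        Method for variables not named in ``spec``.

    Categories are ordered lexicographically, so codes and generated columns
    are deterministic.  One-hot columns are named ``<var>_<category>`` (a
    numeric suffix disambiguates collisions).
    """
    if default_method not in METHODS:
        raise ValueError(f"unknown encoding method {default_method!r}")
    new = frame.copy()
    if spec is None:
        spec = {name: default_method for name in new.var_names
                if new.var.at[name, "kind"] in ("categorical", "boolean")
                and new.var.at[name, "encoding_state"] == "raw"}
    else:
        spec = dict(spec)
    for name, method in spec.items():
        if name not in new.var_names:
            raise KeyError(name)
        if method not in METHODS:
            raise ValueError(f"unknown encoding method {method!r}")
        if new.var.at[name, "kind"] not in ("categorical", "boolean"):
            raise ValidationError(
                f"variable {name!r} is {new.var.at[name, 'kind']}, "
                "only categorical/boolean variables can be encoded")
        if new.var.at[name, "encoding_state"] != "raw":
            raise ValidationError(f"variable {name!r} is already encoded")
    if not spec:
        return new

    store = _encoding_store(new)
    # rebuild X column-block by column-block so one-hot expansion stays in
    # place
    blocks, var_rows = [], []
    for name in new.var_names:
        col = new.X[:, new.col_index(name)]
        if name not in spec:
            blocks.append(col.reshape(-1, 1))
            var_rows.append(new.var.loc[[name]])
            continue
        method = spec[name]
        missing = pd.isna(np.asarray(col, dtype=object))
        raw = np.array([np.nan if m else str(v)
                        for v, m in zip(col, missing)], dtype=object)
        categories = sorted({str(v) for v, m in zip(col, missing) if not m})
        if not categories:
            raise ValidationError(f"variable {name!r} has no observed values")
        entry = {"method": method, "categories": categories,
                 "values": ["" if m else str(v)
                            for v, m in zip(raw, missing)],
                 "missing": [bool(m) for m in missing],
                 "kind": str(new.var.at[name, "kind"])}
        if method == "label":
            codes = {c: float(i) for i, c in enumerate(categories)}
            out = np.array([np.nan if m else codes[str(v)]
                            for v, m in zip(col, missing)], dtype=object)
            blocks.append(out.reshape(-1, 1))
            row = new.var.loc[[name]].copy()
            row["encoding_state"] = "label"
            var_rows.append(row)
            entry["columns"] = [name]
        else:
            existing = set(new.var_names) | {r.index[0] for r in var_rows}
            colnames = []
            for c in categories:
                base = f"{name}_{c}"
                cand, k = base, 1
                while cand in existing or cand in colnames:
                    cand = f"{base}_{k}"
                    k += 1
                colnames.append(cand)
            block = np.empty((new.n_obs, len(categories)), dtype=object)
            for i, (v, m) in enumerate(zip(col, missing)):
                if m:
                    block[i, :] = np.nan
                else:
                    block[i, :] = 0.0
                    block[i, categories.index(str(v))] = 1.0
            blocks.append(block)
            rows = pd.DataFrame(
                {"kind": str(new.var.at[name, "kind"]),
                 "encoding_state": "one_hot"},
                index=pd.Index(colnames))
            for extra in new.var.columns:
                if extra not in rows.columns:
                    rows[extra] = new.var.at[name, extra]
            var_rows.append(rows[new.var.columns])
            entry["columns"] = colnames
        store[name] = entry
        new.set_categories(name, categories)
    X = np.concatenate(blocks, axis=1)
    var = pd.concat(var_rows)
    out = EHRFrame(X, new.obs, var, layers={}, obsm=new.obsm,
                   varm={}, obsp=new.obsp, uns=new.uns)
    out.compact()
    return out


def decode(frame: EHRFrame, variables=None) -> EHRFrame:
    """Restore original categorical columns from their encoding.

    ``variables`` defaults to every encoded variable.  Generated one-hot
    columns are removed; label columns are replaced in place.  Values,
    including missing entries, are restored exactly.
    """
    store = dict(frame.uns.get("ehrkit", {}).get("encoding", {}))
    if variables is None:
        variables = list(store)
    else:
        variables = list(variables)
        for name in variables:
            if name not in store:
                raise StateError(f"no encoding map for variable {name!r}")
    if not variables:
        return frame.copy()
    new = frame.copy()
    blocks, var_rows, consumed = [], [], {}
    for name in variables:
        for c in store[name]["columns"]:
            consumed[c] = name
    done = set()
    for name in new.var_names:
        owner = consumed.get(name)
        if owner is None:
            blocks.append(new.X[:, new.col_index(name)].reshape(-1, 1))
            var_rows.append(new.var.loc[[name]])
            continue
        if owner in done:
            continue
        done.add(owner)
        entry = store[owner]
        raw = np.array([np.nan if m else str(v)
                        for v, m in zip(entry["values"], entry["missing"])],
                       dtype=object)
        blocks.append(raw.reshape(-1, 1))
        row = pd.DataFrame({"kind": entry["kind"], "encoding_state": "raw"},
                           index=pd.Index([owner]))
        for extra in new.var.columns:
            if extra not in row.columns:
                row[extra] = np.nan
        var_rows.append(row[new.var.columns])
    X = np.concatenate(blocks, axis=1)
    var = pd.concat(var_rows)
    enc = _encoding_store(new)
    for name in variables:
        enc.pop(name, None)
    out = EHRFrame(X, new.obs, var, layers={}, obsm=new.obsm, varm={},
                   obsp=new.obsp, uns=new.uns)
    out.compact()
    return out
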