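"""Annotated mixed-type data container for patient-visit tables.

The central object is :class:`EHRFrame`, an observations x variables matrix
(rows are patient visits, columns are measured quantities) carrying aligned
per-observation and per-variable annotation tables, named layers, embedding
matrices, pairwise observation relations and a free-form results store.  The
layout mirrors the AnnData convention used throughout the scientific Python
ecosystem so stores written by :func:`write_store` open in third-party
readers.

Values in the main matrix are floats for numeric variables and strings for
raw categorical / boolean / datetime / text variables; the single missing
marker is NaN for every variable kind.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "FeatureSchema",
    "EHRFrame",
    "read_tabular",
    "infer_feature_types",
    "write_store",
    "read_store",
    "move_to_obs",
    "move_to_x",
]

KINDS = ("numeric", "categorical", "boolean", "datetime", "text")
ENCODING_STATES = ("raw", "one_hot", "label")

#: token pairs recognised as boolean variables (checked case-insensitively)
BOOLEAN_TOKEN_SETS = (
    frozenset({"0", "1"}),
    frozenset({"true", "false"}),
    frozenset({"yes", "no"}),
)

_NA_TOKENS = ["", "NA", "N/A", "NaN", "nan", "null", "NULL"]


@dataclass
class FeatureSchema:
    """Per-variable typing and encoding bookkeeping.

    Parameters
    ----------
    name
        Variable identifier.
    kind
        One of ``numeric``, ``categorical``, ``boolean``, ``datetime``,
        ``text``.
    encoding_state
        ``raw`` until :func:`ehrkit.encode.encode` converts the variable;
        then ``one_hot`` or ``label``.
    source_categories
        Ordered category list; present for categorical/boolean variables and
        required whenever ``encoding_state != "raw"``.
    """

    name: str
    kind: str
    encoding_state: str = "raw"
    source_categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown variable kind {self.kind!r}")
        if self.encoding_state not in ENCODING_STATES:
            raise ValidationError(
                f"unknown encoding state {self.encoding_state!r}"
            )
        if self.encoding_state != "raw" and not self.source_categories:
            raise ValidationError(
                f"{self.name}: encoded variables need source_categories"
            )
        if self.kind == "numeric" and self.encoding_state != "raw":
            raise ValidationError(
                f"{self.name}: numeric variables cannot be encoded"
            )


def _is_missing(values) -> np.ndarray:
    return pd.isna(np.asarray(values, dtype=object))


class EHRFrame:
    """Observations x variables matrix with aligned annotations.

    Attributes
    ----------
    X : numpy.ndarray
        ``n_obs x n_vars`` value matrix.  dtype float64 when every variable
        holds numeric values, otherwise object (strings + floats).  NaN marks
        missing entries in both representations.
    obs : pandas.DataFrame
        Per-observation annotations, indexed by unique string identifiers.
    var : pandas.DataFrame
        Per-variable annotations; always carries ``kind`` and
        ``encoding_state`` columns.
    layers : dict[str, numpy.ndarray]
        Named matrices with the same shape as ``X``.
    obsm, varm : dict[str, numpy.ndarray]
        Named matrices with ``n_obs`` (resp. ``n_vars``) rows, e.g.
        embeddings and component loadings.
    obsp : dict[str, scipy.sparse matrix or numpy.ndarray]
        Named ``n_obs x n_obs`` pairwise relations (neighbor graphs).
    uns : dict
        Free-form keyed results (encoding maps, category lists, parameters).
    """

    def __init__(self, X, obs=None, var=None, layers=None, obsm=None,
                 varm=None, obsp=None, uns=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D matrix")
        n_obs, n_vars = X.shape
        if obs is None:
            obs = pd.DataFrame(index=[str(i) for i in range(n_obs)])
        if var is None:
            var = pd.DataFrame(index=[str(j) for j in range(n_vars)])
        obs = obs.copy()
        var = var.copy()
        obs.index = obs.index.astype(str)
        var.index = var.index.astype(str)
        if "kind" not in var.columns:
            var["kind"] = [
                "numeric" if _column_is_float(X[:, j]) else "text"
                for j in range(n_vars)
            ]
        if "encoding_state" not in var.columns:
            var["encoding_state"] = "raw"
        self.X = X
        self.obs = obs
        self.var = var
        self.layers = dict(layers or {})
        self.obsm = dict(obsm or {})
        self.varm = dict(varm or {})
        self.obsp = dict(obsp or {})
        self.uns = dict(uns or {})
        self.uns.setdefault("ehrkit", {}).setdefault("categories", {})
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def obs_names(self) -> pd.Index:
        return self.obs.index

    @property
    def var_names(self) -> pd.Index:
        return self.var.index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"EHRFrame(n_obs={self.n_obs}, n_vars={self.n_vars}, "
                f"layers={list(self.layers)}, obsm={list(self.obsm)})")

    def copy(self) -> "EHRFrame":
        new = EHRFrame.__new__(EHRFrame)
        new.X = self.X.copy()
        new.obs = self.obs.copy()
        new.var = self.var.copy()
        new.layers = {k: v.copy() for k, v in self.layers.items()}
        new.obsm = {k: v.copy() for k, v in self.obsm.items()}
        new.varm = {k: v.copy() for k, v in self.varm.items()}
        new.obsp = {k: v.copy() for k, v in self.obsp.items()}
        new.uns = _copy.deepcopy(self.uns)
        return new

    # -- schemas -------------------------------------------------------------
    def schema(self, name: str) -> FeatureSchema:
        if name not in self.var.index:
            raise KeyError(name)
        row = self.var.loc[name]
        cats = self.uns["ehrkit"]["categories"].get(name, [])
        return FeatureSchema(name, str(row["kind"]),
                             str(row["encoding_state"]), list(cats))

    def set_categories(self, name: str, categories) -> None:
        self.uns["ehrkit"]["categories"][name] = [str(c) for c in categories]

    # -- column access -------------------------------------------------------
    def col_index(self, name: str) -> int:
        if name not in self.var.index:
            raise KeyError(name)
        return int(self.var.index.get_loc(name))

    def get_values(self, name: str) -> np.ndarray:
        """Raw column values (floats or strings, NaN missing)."""
        return self.X[:, self.col_index(name)].copy()

    def set_values(self, name: str, values) -> None:
        values = np.asarray(values, dtype=object)
        if len(values) != self.n_obs:
            raise ValidationError("column length mismatch")
        j = self.col_index(name)
        if self.X.dtype != object and not _column_is_float(values):
            self.X = self.X.astype(object)
        if self.X.dtype == object:
            self.X[:, j] = values
        else:
            self.X[:, j] = values.astype(np.float64)

    def numeric_var_names(self) -> list[str]:
        """Variables whose matrix values are numeric (native or encoded)."""
        return [n for n in self.var.index
                if _column_is_float(self.X[:, self.col_index(n)])]

    def numeric_matrix(self, variables=None) -> tuple[np.ndarray, list[str]]:
        """Float64 copy of the requested numeric-valued columns."""
        if variables is None:
            variables = self.numeric_var_names()
        cols = []
        for name in variables:
            vals = self.X[:, self.col_index(name)]
            if not _column_is_float(vals):
                raise ValidationError(f"variable {name!r} is not numeric")
            cols.append(np.array(
                [np.nan if pd.isna(v) else float(v) for v in vals],
                dtype=np.float64))
        if not cols:
            return np.empty((self.n_obs, 0)), []
        return np.column_stack(cols), list(variables)

    def set_numeric_matrix(self, matrix: np.ndarray, variables) -> None:
        matrix = np.asarray(matrix, dtype=np.float64)
        for k, name in enumerate(variables):
            self.set_values(name, matrix[:, k])
        self.compact()

    def compact(self) -> None:
        """Demote object X back to float64 when all values are numeric."""
        if self.X.dtype == object and all(
                _column_is_float(self.X[:, j]) for j in range(self.n_vars)):
            out = np.empty(self.shape, dtype=np.float64)
            for j in range(self.n_vars):
                col = self.X[:, j]
                out[:, j] = [np.nan if pd.isna(v) else float(v) for v in col]
            self.X = out

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        n_obs, n_vars = self.X.shape
        if len(self.obs) != n_obs:
            raise ValidationError("obs table not aligned with X rows")
        if len(self.var) != n_vars:
            raise ValidationError("var table not aligned with X columns")
        if self.obs.index.has_duplicates:
            raise ValidationError("duplicate observation identifiers")
        if self.var.index.has_duplicates:
            raise ValidationError("duplicate variable identifiers")
        for name, layer in self.layers.items():
            if layer.shape != self.X.shape:
                raise ValidationError(f"layer {name!r} shape mismatch")
        for name, m in self.obsm.items():
            if m.shape[0] != n_obs:
                raise ValidationError(f"obsm {name!r} row mismatch")
        for name, m in self.varm.items():
            if m.shape[0] != n_vars:
                raise ValidationError(f"varm {name!r} row mismatch")
        for name, m in self.obsp.items():
            if m.shape != (n_obs, n_obs):
                raise ValidationError(f"obsp {name!r} shape mismatch")

    # -- subsetting ----------------------------------------------------------
    def subset_obs(self, mask_or_index) -> "EHRFrame":
        """New frame restricted to the given observations (bool mask,
        integer positions, or observation names)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            pos = np.flatnonzero(idx)
        elif idx.dtype.kind in "iu":
            pos = idx
        else:
            pos = np.array([self.obs.index.get_loc(str(i)) for i in idx])
        new = self.copy()
        new.X = new.X[pos]
        new.obs = new.obs.iloc[pos]
        new.layers = {k: v[pos] for k, v in new.layers.items()}
        new.obsm = {k: v[pos] for k, v in new.obsm.items()}
        new.obsp = {}  # pairwise relations are invalidated by row selection
        return new


def _column_is_float(col: np.ndarray) -> bool:
    if col.dtype != object:
        return np.issubdtype(col.dtype, np.number) or np.issubdtype(
            col.dtype, np.bool_)
    for v in col:
        if pd.isna(v):
            continue
        if not isinstance(v, (int, float, np.integer, np.floating, np.bool_,
                              bool)):
            return False
    return True


# ---------------------------------------------------------------------------
# type inference
# ---------------------------------------------------------------------------

def _infer_column_kind(values: pd.Series, max_categories: int = 100) -> str:
    """Decide the kind of a raw string/float column.

    Order of the rules: boolean token sets, fully numeric, fully
    date-parseable, at most ``max_categories`` distinct tokens, else text.
    """
    non_na = values.dropna().astype(str)
    if non_na.empty:
        return "numeric"
    tokens = frozenset(t.lower() for t in non_na.unique())
    if any(tokens <= s for s in BOOLEAN_TOKEN_SETS):
        return "boolean"
    numeric = pd.to_numeric(non_na, errors="coerce")
    if not numeric.isna().any():
        return "numeric"
    with pd.option_context("mode.chained_assignment", None):
        try:
            parsed = pd.to_datetime(non_na, errors="coerce", format="mixed")
        except Exception:
            parsed = pd.Series([pd.NaT] * len(non_na))
    if not parsed.isna().any():
        return "datetime"
    if non_na.nunique() <= max_categories:
        return "categorical"
    return "text"


def _coerce_column(values: pd.Series, kind: str) -> np.ndarray:
    """Column values under a kind: floats for numeric and numeric-token
    booleans, strings otherwise; NaN for missing."""
    out = np.empty(len(values), dtype=object)
    for i, v in enumerate(values):
        if pd.isna(v):
            out[i] = np.nan
        elif kind == "numeric":
            out[i] = float(v)
        else:
            out[i] = str(v)
    if kind == "boolean":
        tokens = {str(v).lower() for v in values.dropna()}
        if tokens <= {"0", "1", "0.0", "1.0"}:
            out = np.array([np.nan if pd.isna(v) else float(v) for v in out],
                           dtype=object)
    return out


def read_tabular(path, delimiter: str = ",", index_column: str | None = None,
                 type_overrides: dict[str, str] | None = None,
                 max_categories: int = 100) -> EHRFrame:
    """Read a delimited patient-visit table into an :class:`EHRFrame`.

    One observation per data row; a header row names the variables.  Variable
    kinds are inferred per column (numeric / boolean / datetime / categorical
    / text) unless overridden via ``type_overrides``.  Empty cells and common
    NA tokens become the NaN missing marker.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, engine="python",
                         keep_default_na=False, na_values=_NA_TOKENS,
                         skipinitialspace=True, skip_blank_lines=False)
    except OSError:
        raise
    except pd.errors.ParserError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    type_overrides = dict(type_overrides or {})
    for name in type_overrides:
        if name not in df.columns:
            raise KeyError(f"type override names absent column {name!r}")
    if index_column is not None:
        if index_column not in df.columns:
            raise KeyError(index_column)
        obs_index = df[index_column].astype(str).tolist()
        df = df.drop(columns=[index_column])
    else:
        obs_index = [str(i) for i in range(len(df))]

    n_obs, n_vars = df.shape
    X = np.empty((n_obs, n_vars), dtype=object)
    kinds, missing_frac = [], []
    categories: dict[str, list[str]] = {}
    for j, name in enumerate(df.columns):
        col = df[name]
        kind = type_overrides.get(name) or _infer_column_kind(
            col, max_categories)
        if kind not in KINDS:
            raise ValidationError(f"unknown kind override {kind!r}")
        X[:, j] = _coerce_column(col, kind)
        kinds.append(kind)
        missing_frac.append(float(col.isna().mean()) if n_obs else 0.0)
        if kind in ("categorical", "boolean"):
            categories[name] = sorted(
                {str(v) for v in X[:, j] if not pd.isna(v)})
    var = pd.DataFrame({"kind": kinds, "encoding_state": "raw",
                        "missing_fraction": missing_frac},
                       index=pd.Index(df.columns.astype(str), name="variable"))
    obs = pd.DataFrame(index=pd.Index(obs_index, name="observation"))
    frame = EHRFrame(X, obs, var)
    frame.uns["ehrkit"]["categories"] = categories
    frame.compact()
    return frame


def infer_feature_types(frame: EHRFrame,
                        max_categories: int = 100) -> EHRFrame:
    """(Re-)infer every variable's kind from its current raw values."""
    if frame.n_vars == 0 or frame.n_obs == 0:
        raise ValidationError("cannot infer feature types on an empty frame")
    new = frame.copy()
    for name in new.var_names:
        if new.var.at[name, "encoding_state"] != "raw":
            continue
        col = pd.Series(new.get_values(name), dtype=object)
        kind = _infer_column_kind(col, max_categories)
        new.var.at[name, "kind"] = kind
        new.set_values(name, _coerce_column(col, kind))
        if kind in ("categorical", "boolean"):
            new.set_categories(
                name, sorted({str(v) for v in col.dropna()}))
    new.compact()
    return new


# ---------------------------------------------------------------------------
# hierarchical store (h5ad-compatible layout)
# ---------------------------------------------------------------------------

_STR_MISSING = "__ehrkit_missing__"


def write_store(frame: EHRFrame, path) -> None:
    """Write a frame to an h5ad-layout hierarchical store.

    Numeric values are stored bitwise in ``X``; raw string-valued variables
    (categorical, boolean tokens, datetime, text) are stored alongside in the
    unstructured group with explicit missing masks so that
    :func:`read_store` round-trips the frame exactly.
    """
    import anndata as ad

    frame.validate()
    n_obs, n_vars = frame.shape
    X = np.full((n_obs, n_vars), np.nan, dtype=np.float64)
    nonnum_values, nonnum_mask, nonnum_names = [], [], []
    for j, name in enumerate(frame.var_names):
        col = frame.X[:, j]
        if _column_is_float(col):
            X[:, j] = [np.nan if pd.isna(v) else float(v) for v in col]
        else:
            mask = _is_missing(col)
            vals = np.array([_STR_MISSING if m else str(v)
                             for v, m in zip(col, mask)], dtype=object)
            nonnum_names.append(str(name))
            nonnum_values.append(vals.astype(str))
            nonnum_mask.append(mask)
    uns = _copy.deepcopy(frame.uns)
    uns["ehrkit_nonnumeric"] = {
        name: {"values": vals, "mask": mask.astype(bool)}
        for name, vals, mask in zip(nonnum_names, nonnum_values, nonnum_mask)
    }
    obs = frame.obs.copy()
    var = frame.var.copy()
    for df in (obs, var):
        for c in df.columns:
            if df[c].dtype == object:
                df[c] = df[c].astype(str).where(~df[c].isna(), other=np.nan)
    adata = ad.AnnData(X=X, obs=obs, var=var, uns=uns,
                       layers={k: np.asarray(v, dtype=np.float64)
                               for k, v in frame.layers.items()},
                       obsm=dict(frame.obsm), varm=dict(frame.varm),
                       obsp=dict(frame.obsp))
    adata.write_h5ad(path)


def read_store(path) -> EHRFrame:
    """Read a store written by :func:`write_store`."""
    import anndata as ad

    try:
        adata = ad.read_h5ad(path)
    except OSError:
        raise
    except Exception as exc:  # corrupt store
        raise FormatError(f"could not open store {path}: {exc}") from exc
    uns = dict(adata.uns)
    nonnum = uns.pop("ehrkit_nonnumeric", {})
    X_num = np.asarray(adata.X, dtype=np.float64)
    obs = _plain_table(adata.obs)
    var = _plain_table(adata.var)
    if len(nonnum) == 0:
        X = X_num
    else:
        X = X_num.astype(object)
        for i in range(X.shape[0]):
            for j in range(X.shape[1]):
                if np.isnan(X_num[i, j]):
                    X[i, j] = np.nan
        for name, payload in nonnum.items():
            j = int(var.index.get_loc(str(name)))
            vals = np.asarray(payload["values"]).astype(str)
            mask = np.asarray(payload["mask"]).astype(bool)
            col = np.array([np.nan if m else v
                            for v, m in zip(vals, mask)], dtype=object)
            X[:, j] = col
    uns = _plain_uns(uns)
    frame = EHRFrame(X, obs, var,
                     layers={k: np.asarray(v) for k, v in
                             adata.layers.items()},
                     obsm={k: np.asarray(v) for k, v in adata.obsm.items()},
                     varm={k: np.asarray(v) for k, v in adata.varm.items()},
                     obsp=dict(adata.obsp), uns=uns)
    return frame


def _plain_table(df: pd.DataFrame) -> pd.DataFrame:
    """Undo anndata's categorical coercion so tables compare as written."""
    out = df.copy()
    for c in out.columns:
        if isinstance(out[c].dtype, pd.CategoricalDtype):
            out[c] = out[c].astype(object)
        if out[c].dtype == object:
            out[c] = out[c].where(out[c] != "nan", other=np.nan)
    out.index = out.index.astype(str)
    return out


def _plain_uns(obj):
    """Recursively convert h5ad uns payloads to plain Python containers."""
    if isinstance(obj, dict) or hasattr(obj, "keys"):
        return {str(k): _plain_uns(obj[k]) for k in obj.keys()}
    if isinstance(obj, np.ndarray):
        if obj.dtype.kind in "SU" or obj.dtype == object:
            return [str(v) for v in obj.tolist()]
        return obj
    if isinstance(obj, (np.generic,)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_plain_uns(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# moving variables between X and obs
# ---------------------------------------------------------------------------

def move_to_obs(frame: EHRFrame, variables) -> EHRFrame:
    """Move variables out of the data matrix into the obs table.

    Encoded variables are decoded first so the obs table receives the
    original values.  Typical use: keep outcome or sensitive variables out of
    embedding and model computations while retaining them for analysis.
    """
    variables = list(variables)
    enc_map = frame.uns.get("ehrkit", {}).get("encoding", {})
    for name in variables:
        if name not in frame.var_names and name not in enc_map:
            raise KeyError(name)
    if not variables:
        return frame.copy()
    from .encode import decode

    encoded = [n for n in variables
               if n in enc_map
               or frame.var.at[n, "encoding_state"] != "raw"]
    new = decode(frame, encoded) if encoded else frame.copy()
    keep = [n for n in new.var_names if n not in variables]
    obs = new.obs.copy()
    for name in variables:
        obs[name] = new.get_values(name)
    keep_pos = [new.col_index(n) for n in keep]
    X = new.X[:, keep_pos]
    var = new.var.loc[keep]
    layers = {k: v[:, keep_pos] for k, v in new.layers.items()}
    out = EHRFrame(X, obs, var, layers=layers, obsm=new.obsm, varm={},
                   obsp=new.obsp, uns=new.uns)
    out.compact()
    return out


def move_to_x(frame: EHRFrame, obs_columns,
              max_categories: int = 100) -> EHRFrame:
    """Move obs-table columns into the data matrix with inferred schemas."""
    obs_columns = list(obs_columns)
    for name in obs_columns:
        if name not in frame.obs.columns:
            raise KeyError(name)
        if name in frame.var_names:
            raise ValidationError(
                f"variable {name!r} already exists in the data matrix")
    if not obs_columns:
        return frame.copy()
    new = frame.copy()
    X = new.X.astype(object) if new.X.dtype != object else new.X.copy()
    cols, kinds = [], []
    for name in obs_columns:
        series = pd.Series(new.obs[name].to_numpy(), dtype=object)
        kind = _infer_column_kind(series, max_categories)
        cols.append(_coerce_column(series, kind))
        kinds.append(kind)
        if kind in ("categorical", "boolean"):
            new.set_categories(name, sorted({str(v) for v in
                                             series.dropna()}))
    X = np.column_stack([X] + cols) if new.n_vars else np.column_stack(cols)
    var = pd.concat([
        new.var,
        pd.DataFrame({"kind": kinds, "encoding_state": "raw"},
                     index=pd.Index(obs_columns)),
    ])
    obs = new.obs.drop(columns=obs_columns)
    pad = {k: np.column_stack(
        [v, np.full((new.n_obs, len(obs_columns)), np.nan)])
        for k, v in new.layers.items()}
    out = EHRFrame(X, obs, var, layers=pad, obsm=new.obsm, varm={},
                   obsp=new.obsp, uns=new.uns)
    out.compact()
    return out
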