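"""Lower-dimensional patient landscape: feature selection, PCA, neighbor
graph, UMAP embedding and Leiden clustering.

Each step writes its parameters into the frame's unstructured store so a
pipeline is auditable, and stores its output in the conventional slots
(``obsm['X_pca']``, ``obsp['distances']``/``obsp['connectivities']``,
``obsm['X_umap']``, ``obs['leiden']``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .core import EHRFrame
from .errors import StateError, ValidationError

__all__ = ["highly_variable_features", "pca", "neighbors", "umap_embed",
           "cluster_leiden"]


def highly_variable_features(frame: EHRFrame, n_top: int) -> EHRFrame:
    """Flag the ``n_top`` most dispersed variables.

    Dispersion is the variance of non-missing values; constant variables
    have zero dispersion and are never flagged ahead of varying ones.  The
    flag is written to ``var['highly_variable']``.
    """
    if n_top > frame.n_vars:
        raise ValueError("n_top exceeds the number of variables")
    new = frame.copy()
    M, names = new.numeric_matrix()
    disp = np.full(new.n_vars, -np.inf)
    for name, col in zip(names, M.T):
        obs = col[~np.isnan(col)]
        disp[new.col_index(name)] = float(np.var(obs)) if obs.size > 1 \
            else 0.0
    order = np.argsort(-disp, kind="stable")
    flag = np.zeros(new.n_vars, dtype=bool)
    flag[order[:n_top]] = True
    new.var["highly_variable"] = flag
    new.var["dispersion"] = np.where(np.isfinite(disp), disp, np.nan)
    return new


def pca(frame: EHRFrame, n_components: int = 50) -> EHRFrame:
    """Principal-component scores of the (centered, not rescaled) matrix.

    Requires a complete numeric matrix: impute first.  Scores go to
    ``obsm['X_pca']``, loadings to ``varm['PCs']`` and explained-variance
    ratios to ``uns['pca']``.
    """
    from sklearn.decomposition import PCA

    new = frame.copy()
    M, names = new.numeric_matrix()
    if len(names) != new.n_vars:
        raise ValidationError("pca requires a fully numeric matrix; "
                              "encode categoricals first")
    if np.isnan(M).any():
        raise ValidationError("missing values present; impute before pca")
    n_components = min(n_components, min(M.shape))
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(M)
    new.obsm["X_pca"] = scores
    new.varm["PCs"] = model.components_.T
    new.uns["pca"] = {
        "variance_ratio": model.explained_variance_ratio_,
        "variance": model.explained_variance_,
        "mean": model.mean_,
        "n_components": n_components,
    }
    return new


def neighbors(frame: EHRFrame, k: int = 15,
              use_representation: str = "X_pca",
              metric: str = "euclidean") -> EHRFrame:
    """k-nearest-neighbor graph on a stored representation.

    ``use_representation`` names an obsm matrix, or ``"X"`` for the data
    matrix itself.  Distances (excluding self) go to ``obsp['distances']``;
    ``obsp['connectivities']`` is the union-symmetrized adjacency.
    """
    if k >= frame.n_obs:
        raise ValueError("k must be smaller than the number of observations")
    from sklearn.neighbors import NearestNeighbors

    new = frame.copy()
    if use_representation == "X":
        R, _ = new.numeric_matrix()
        if np.isnan(R).any():
            raise ValidationError("missing values present; impute first")
    elif use_representation in new.obsm:
        R = np.asarray(new.obsm[use_representation], dtype=float)
    else:
        raise StateError(f"representation {use_representation!r} not found")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric)
    nn.fit(R)
    dist, idx = nn.kneighbors(R)
    n = new.n_obs
    rows = np.repeat(np.arange(n), k)
    # drop self-edges (first neighbor); keep k true neighbors
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    D = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = sparse.csr_matrix((np.ones_like(vals), (rows, cols)), shape=(n, n))
    C = A.maximum(A.T)  # union symmetrization
    new.obsp["distances"] = D
    new.obsp["connectivities"] = C
    new.uns["neighbors"] = {"k": k, "metric": metric,
                            "use_representation": use_representation}
    return new


def umap_embed(frame: EHRFrame, n_components: int = 2,
               seed: int = 0, min_dist: float = 0.5) -> EHRFrame:
    """UMAP embedding of the representation used for the neighbor graph.

    Deterministic for a fixed seed.  Output in ``obsm['X_umap']``.
    """
    if "neighbors" not in frame.uns or "connectivities" not in frame.obsp:
        raise StateError("run neighbors() before umap_embed()")
    import umap

    new = frame.copy()
    params = new.uns["neighbors"]
    rep = params["use_representation"]
    if rep == "X":
        R, _ = new.numeric_matrix()
    else:
        R = np.asarray(new.obsm[rep], dtype=float)
    k = int(params["k"])
    model = umap.UMAP(n_components=n_components,
                      n_neighbors=max(2, min(k, new.n_obs - 1)),
                      min_dist=min_dist, metric=params["metric"],
                      random_state=seed)
    new.obsm["X_umap"] = np.asarray(model.fit_transform(R), dtype=np.float64)
    new.uns["umap"] = {"n_components": n_components, "seed": seed,
                       "min_dist": min_dist}
    return new


def cluster_leiden(frame: EHRFrame, resolution: float = 1.0,
                   seed: int = 0, key_added: str = "leiden") -> EHRFrame:
    """Leiden community detection on the neighbor graph.

    Uses the RB-configuration quality function with the given resolution.
    Labels are contiguous integers starting at 0, stored as a categorical
    obs column; deterministic for a fixed seed.
    """
    if "connectivities" not in frame.obsp:
        raise StateError("run neighbors() before cluster_leiden()")
    import igraph as ig
    import leidenalg

    new = frame.copy()
    C = sparse.coo_matrix(sparse.triu(new.obsp["connectivities"]))
    g = ig.Graph(n=new.n_obs, edges=list(zip(C.row, C.col)),
                 edge_attrs={"weight": C.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=2)
    labels = np.asarray(part.membership)
    # relabel so cluster ids are contiguous and ordered by first appearance
    _, labels = np.unique(labels, return_inverse=True)
    new.obs[key_added] = pd.Categorical([str(v) for v in labels])
    new.uns[key_added] = {"resolution": resolution, "seed": seed}
    return new
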