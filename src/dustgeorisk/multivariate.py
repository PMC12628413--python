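"""Unsupervised source apportionment: rotated PCA and hierarchical clustering.

PCA is run on the element correlation matrix (i.e. on z-scored
concentrations); components with unrotated eigenvalue > 1 are retained and
varimax-rotated with Kaiser normalization.  Explained variance per rotated
component is the rotated sum of squared loadings divided by the number of
elements.  Rotation redistributes variance among the retained components
but preserves each element's communality and the retained total.

Hierarchical clustering runs in two modes: elements are clustered by Ward
linkage on correlation distance (1 - r), samples by Ward linkage on
squared Euclidean distance over z-scored concentrations (raw mg/kg would
reduce the geometry to the Fe axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .data_io import ConcentrationTable

STRONG_LOADING = 0.70


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Varimax rotation of a p x k loading matrix (SVD-based sweeps)."""
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L ** 2).sum(axis=1))
    if kaiser_normalize:
        L = L / h[:, None]
    R = np.eye(k)
    obj = 0.0
    for _ in range(max_iter):
        Lam = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lam ** 3 - Lam @ np.diag((Lam ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        obj, obj_old = s.sum(), obj
        if obj_old != 0 and obj / obj_old < 1 + tol:
            break
    L = L @ R
    if kaiser_normalize:
        L = L * h[:, None]
    return L


@dataclass(frozen=True)
class PcaResult:
    n_retained: int
    eigenvalues: pd.Series            # all p unrotated eigenvalues
    loadings: pd.DataFrame            # rotated, element x component
    unrotated_loadings: pd.DataFrame
    rotated_ssl: pd.Series            # rotation sums of squared loadings
    explained_pct: pd.Series          # per rotated component, % of total
    cumulative_pct: pd.Series
    strong: pd.DataFrame              # |loading| >= 0.70 flags


def pca_varimax(table: ConcentrationTable) -> PcaResult:
    """Correlation-matrix PCA, eigenvalue > 1 retention, varimax rotation."""
    X = table.data
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 elements and >= 3 samples")
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    p = len(eigval)
    k = int((eigval > 1).sum())
    if k < 1:
        raise ValueError("no component with eigenvalue > 1; PCA degenerate")

    unrot = eigvec[:, :k] * np.sqrt(eigval[:k])
    rot = varimax(unrot)
    # sign convention: each component's largest-magnitude loading positive
    for j in range(rot.shape[1]):
        if rot[np.argmax(np.abs(rot[:, j])), j] < 0:
            rot[:, j] *= -1
    ssl = (rot ** 2).sum(axis=0)
    comp_order = np.argsort(ssl)[::-1]
    rot, ssl = rot[:, comp_order], ssl[comp_order]

    comps = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(rot, index=X.columns, columns=comps)
    explained = pd.Series(100 * ssl / p, index=comps)
    return PcaResult(
        n_retained=k,
        eigenvalues=pd.Series(eigval, index=[f"PC{i + 1}" for i in range(p)]),
        loadings=loadings,
        unrotated_loadings=pd.DataFrame(unrot, index=X.columns, columns=comps),
        rotated_ssl=pd.Series(ssl, index=comps),
        explained_pct=explained,
        cumulative_pct=explained.cumsum(),
        strong=loadings.abs() >= STRONG_LOADING,
    )


@dataclass(frozen=True)
class HcaResult:
    mode: str                  # "elements" | "samples"
    metric: str
    linkage_matrix: np.ndarray  # scipy merge table (dendrogram-ready)
    labels: list[str]

    def clusters(self, k: int) -> dict[str, int]:
        flat = fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def hca(
    table: ConcentrationTable, mode: str = "elements", standardize: bool = True
) -> HcaResult:
    """Ward-linkage hierarchical clustering of elements or samples."""
    X = table.data
    if mode == "elements":
        sd = X.std(ddof=1)
        if (sd == 0).any():
            bad = sd.index[sd == 0].tolist()
            raise ValueError(f"constant element(s) {bad}: correlation distance undefined")
        R = np.corrcoef(X.to_numpy(), rowvar=False)
        dist = squareform(1 - R, checks=False)
        Z = linkage(dist, method="ward")
        return HcaResult("elements", "correlation (1 - r)", Z, list(X.columns))
    if mode == "samples":
        M = X.to_numpy(dtype=float)
        if standardize:
            M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
        Z = linkage(pdist(M, metric="sqeuclidean"), method="ward")
        return HcaResult("samples", "squared Euclidean", Z, list(X.index))
    raise ValueError(f"unknown mode {mode!r}")
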