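"""Low-dimensional embedding of stacked structure-function feature matrices.

PCA and Laplacian Eigenmaps are implemented in-repo and are deterministic;
t-SNE and UMAP delegate to scikit-learn and umap-learn with an explicit seed
and are labeled stochastic. All time points are embedded *jointly* (rows
concatenated, one embedding, split back), so the per-time-point coordinates
share one space and are mutually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .errors import AlignmentError, ValidationError

__all__ = ["Embedding", "PhasePlaneTrajectory", "pca", "laplacian_eigenmaps",
           "embed_joint", "phase_plane"]

METHODS = ("pca", "le", "tsne", "umap")


@dataclass
class Embedding:
    """Joint embedding: one (n*T) x d coordinate block plus row labels."""

    coordinates: np.ndarray          # (n*T, d)
    timepoints: np.ndarray           # timepoint label per row
    method: str
    params: dict = field(default_factory=dict)
    stochastic: bool = False

    def per_timepoint(self) -> dict:
        return {t: self.coordinates[self.timepoints == t]
                for t in pd.unique(self.timepoints)}

    def to_frame(self, bin_ids: np.ndarray | None = None) -> pd.DataFrame:
        d = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates,
                          columns=[f"dim{i + 1}" for i in range(d)])
        df.insert(0, "timepoint", self.timepoints)
        if bin_ids is not None:
            n = len(bin_ids)
            df.insert(0, "locus", np.tile(bin_ids, len(df) // n))
        return df


@dataclass
class PhasePlaneTrajectory:
    """Per-locus (structure, function) coordinates ordered by time point."""

    loci: np.ndarray
    timepoints: np.ndarray
    structure: np.ndarray            # (n_loci, T)
    function: np.ndarray             # (n_loci, T)
    structure_name: str = "eigenvector centrality"
    function_name: str = "log2 expression"

    def to_frame(self) -> pd.DataFrame:
        rec = []
        for i, locus in enumerate(self.loci):
            for j, t in enumerate(self.timepoints):
                rec.append((locus, t, self.structure[i, j], self.function[i, j]))
        return pd.DataFrame(rec, columns=["locus", "timepoint",
                                          "structure", "function"])


def _fix_signs(scores: np.ndarray, components: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign: the largest-magnitude loading of each component
    is made positive (first index wins ties)."""
    for j in range(components.shape[0]):
        i = int(np.argmax(np.abs(components[j])))
        if components[j, i] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    return scores, components


def pca(X: np.ndarray, d: int = 2, return_components: bool = False):
    """Column-centered SVD principal component scores.

    Deterministic up to the stated sign convention; no whitening.
    """
    X = np.asarray(X, dtype=float)
    if d > min(X.shape):
        raise ValidationError(f"d={d} exceeds min(data shape) {min(X.shape)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :d] * s[:d]
    comps = Vt[:d].copy()
    scores, comps = _fix_signs(scores, comps)
    if return_components:
        return scores, comps, s
    return scores


def _knn_graph(X: np.ndarray, k_neighbors: int, weights: str) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    n = X.shape[0]
    k = min(k_neighbors, n - 1)
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    # connect each point to its k nearest neighbors, including distance ties
    # so duplicated points get identical neighborhoods (deterministic graph)
    kth = np.partition(D, k - 1, axis=1)[:, k - 1]
    adj = D <= kth[:, None] + 1e-12
    W = np.zeros((n, n))
    if weights == "heat":
        finite = D[adj]
        sigma = float(np.median(finite)) or 1.0
        W[adj] = np.exp(-(D[adj] ** 2) / (2 * sigma ** 2))
    elif weights == "binary":
        W[adj] = 1.0
    else:
        raise ValidationError("weights must be 'binary' or 'heat'")
    return np.maximum(W, W.T)        # symmetric union rule


def laplacian_eigenmaps(X: np.ndarray, k_neighbors: int = 15, d: int = 2,
                        weights: str = "binary") -> np.ndarray:
    """Laplacian Eigenmaps on a symmetric k-NN graph.

    Coordinates are eigenvectors 2..d+1 (ascending eigenvalue) of the
    random-walk-normalized graph Laplacian, solved as the generalized problem
    L v = lambda D v. Deterministic: dense solver, index tie-break, and the
    same sign convention as :func:`pca`.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")
    if n < d + 2:
        raise ValidationError(f"need at least d+2={d + 2} points")
    W = _knn_graph(X, k_neighbors, weights)
    n_comp, labels = connected_components(csr_matrix(W), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        if sizes.max() < d + 2:
            raise ValidationError(
                "largest k-NN graph component smaller than d+2; "
                "increase k_neighbors")
    deg = W.sum(axis=1)
    deg[deg == 0] = 1.0
    L = np.diag(deg) - W
    vals, vecs = scipy.linalg.eigh(L, np.diag(deg))
    order = np.argsort(vals, kind="stable")
    Y = vecs[:, order[1:d + 1]].copy()
    Y, _ = _fix_signs(Y, Y.T.copy())
    return Y


def embed_joint(stack: list, method: str = "pca", params: dict | None = None,
                seed: int = 42) -> Embedding:
    """Embed all time points of a normalized feature-matrix stack jointly.

    Rows of every time point are concatenated into one matrix, embedded once,
    and split back, so the T per-time-point coordinate sets live in a common
    space (Algorithm step: common low-dimensional space).
    """
    if method not in METHODS:
        raise ValidationError(
            f"unknown method {method!r}; choose one of {METHODS}")
    params = dict(params or {})
    d = int(params.pop("d", 2))
    mats = [np.asarray(getattr(f, "values", f), dtype=float) for f in stack]
    n = mats[0].shape[0]
    if any(m.shape != mats[0].shape for m in mats):
        raise AlignmentError("all feature matrices must share one shape")
    X = np.vstack(mats)
    tps = np.concatenate([
        np.full(n, getattr(f, "timepoint", i), dtype=float)
        for i, f in enumerate(stack)])
    stochastic = False
    if method == "pca":
        Y = pca(X, d=d)
    elif method == "le":
        Y = laplacian_eigenmaps(X, d=d,
                                k_neighbors=int(params.pop("k_neighbors", 15)),
                                weights=params.pop("weights", "binary"))
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = float(params.pop("perplexity", 30))
        perplexity = min(perplexity, max((X.shape[0] - 1) / 3.0, 2.0))
        Y = TSNE(n_components=d, perplexity=perplexity, random_state=seed,
                 init="pca", **params).fit_transform(X)
        stochastic = True
    else:  # umap
        import umap

        Y = umap.UMAP(n_components=d,
                      n_neighbors=int(params.pop("n_neighbors", 15)),
                      min_dist=float(params.pop("min_dist", 0.1)),
                      random_state=seed, **params).fit_transform(X)
        stochastic = True
    return Embedding(np.asarray(Y, dtype=float), tps, method,
                     params={"d": d, "seed": seed}, stochastic=stochastic)


def phase_plane(structure_series: np.ndarray, function_series: np.ndarray,
                loci: np.ndarray | None = None,
                timepoints: np.ndarray | None = None,
                structure_name: str = "eigenvector centrality",
                function_name: str = "log2 expression"
                ) -> PhasePlaneTrajectory:
    """Pair per-time-point structure and function vectors into trajectories.

    ``structure_series`` and ``function_series`` are (n_loci, T) arrays (or
    lists of length-T vectors); coordinates pass through verbatim.
    """
    S = np.atleast_2d(np.asarray(structure_series, dtype=float))
    F = np.atleast_2d(np.asarray(function_series, dtype=float))
    if S.shape != F.shape:
        raise AlignmentError(
            f"structure {S.shape} and function {F.shape} series differ")
    n, T = S.shape
    if T < 1:
        raise AlignmentError("need at least one timepoint")
    if loci is None:
        loci = np.arange(n)
    if timepoints is None:
        timepoints = np.arange(T, dtype=float)
    order = np.argsort(np.asarray(timepoints), kind="stable")
    return PhasePlaneTrajectory(np.asarray(loci),
                                np.asarray(timepoints)[order],
                                S[:, order], F[:, order],
                                structure_name, function_name)
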