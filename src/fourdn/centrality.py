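"""Weighted-network centrality of the Hi-C contact graph.

Bins are nodes, contact frequencies are edge weights; the diagonal
(self-contact) is excluded. Path-based measures (betweenness, closeness) use
edge length 1/weight by default, so stronger contact means shorter distance;
``-log(w/max w)`` is available as an alternative length transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import ValidationError
from .genome_model import HiCMatrix

__all__ = ["CentralityVector", "degree_centrality", "eigenvector_centrality",
           "betweenness_centrality", "closeness_centrality", "all_centralities"]

KINDS = ("degree", "eigenvector", "betweenness", "closeness")


@dataclass
class CentralityVector:
    kind: str
    values: np.ndarray
    sample: str = ""
    timepoint: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"unknown centrality kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("centrality values must be finite")


def _adjacency(H: HiCMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal adjacency restricted to unmasked bins, plus the mask."""
    m = H.mask
    A = H.values[np.ix_(m, m)].copy()
    np.fill_diagonal(A, 0.0)
    return A, m


def _distance_matrix(A: np.ndarray, transform: str) -> np.ndarray:
    with np.errstate(divide="ignore"):
        if transform == "reciprocal":
            D = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), 0.0)
        elif transform == "neglog":
            wmax = A.max()
            D = np.where(A > 0, -np.log(np.where(A > 0, A, 1.0) / wmax), 0.0)
            # equal-to-max edges get length 0; nudge to a tiny positive length
            D[(A > 0) & (D <= 0)] = np.finfo(float).tiny
        else:
            raise ValidationError(f"unknown distance transform {transform!r}")
    return D


def degree_centrality(H: HiCMatrix) -> CentralityVector:
    """Weighted degree (strength): off-diagonal row sums over unmasked bins."""
    A, m = _adjacency(H)
    out = np.zeros(H.n_bins)
    out[m] = A.sum(axis=1)
    return CentralityVector("degree", out, H.sample, H.timepoint)


def eigenvector_centrality(H: HiCMatrix, tol: float = 1e-10,
                           max_iter: int = 10000) -> CentralityVector:
    """Perron eigenvector of the contact graph, unit Euclidean norm.

    On a disconnected graph the vector is computed on the largest connected
    component (ties broken by lowest node index); other nodes get 0 and a
    warning is emitted.
    """
    A, m = _adjacency(H)
    out = np.zeros(H.n_bins)
    k = A.shape[0]
    if k == 0 or A.max() == 0:
        return CentralityVector("eigenvector", out, H.sample, H.timepoint,
                                {"degenerate": True})
    n_comp, labels = connected_components(csr_matrix(A), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        comp = int(np.argmax(sizes))
        warnings.warn("contact graph disconnected; eigenvector centrality "
                      "computed on the largest component", stacklevel=2)
        sel = labels == comp
    else:
        sel = np.ones(k, dtype=bool)
    Asub = A[np.ix_(sel, sel)]
    v = np.full(Asub.shape[0], 1.0 / np.sqrt(Asub.shape[0]))
    for _ in range(max_iter):
        w = Asub @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            break
        w /= nrm
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    nrm = np.linalg.norm(v)
    if nrm > 0:
        v = v / nrm
    sub = np.zeros(k)
    sub[sel] = v
    out[m] = sub
    return CentralityVector("eigenvector", out, H.sample, H.timepoint,
                            {"n_components": int(n_comp)})


def betweenness_centrality(H: HiCMatrix,
                           distance: str = "reciprocal") -> CentralityVector:
    """Shortest-path betweenness, normalized by (n-1)(n-2)/2 over unmasked n."""
    import igraph as ig

    A, m = _adjacency(H)
    out = np.zeros(H.n_bins)
    k = A.shape[0]
    if k < 3 or A.max() == 0:
        return CentralityVector("betweenness", out, H.sample, H.timepoint)
    D = _distance_matrix(A, distance)
    iu, ju = np.where(np.triu(D, 1) > 0)
    g = ig.Graph(n=k, edges=list(zip(iu.tolist(), ju.tolist())))
    bet = np.array(g.betweenness(weights=D[iu, ju].tolist(), directed=False))
    out[m] = bet / ((k - 1) * (k - 2) / 2.0)
    return CentralityVector("betweenness", out, H.sample, H.timepoint,
                            {"distance": distance})


def closeness_centrality(H: HiCMatrix,
                         distance: str = "reciprocal") -> CentralityVector:
    """Closeness (n-1)/sum_j d(i,j) on weighted shortest-path distances.

    If any pair is unreachable the harmonic form sum_j (1/d(i,j))/(n-1) is
    used for every node instead, flagged in ``meta['harmonic']``. Isolated
    nodes get 0.
    """
    A, m = _adjacency(H)
    out = np.zeros(H.n_bins)
    k = A.shape[0]
    if k == 0 or A.max() == 0:
        return CentralityVector("closeness", out, H.sample, H.timepoint)
    D = _distance_matrix(A, distance)
    sp = dijkstra(csr_matrix(D), directed=False)
    np.fill_diagonal(sp, 0.0)
    harmonic = bool(np.isinf(sp).any())
    vals = np.zeros(k)
    if harmonic:
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(sp) & (sp > 0), 1.0 / sp, 0.0)
        vals = inv.sum(axis=1) / (k - 1) if k > 1 else np.zeros(k)
    else:
        tot = sp.sum(axis=1)
        nz = tot > 0
        vals[nz] = (k - 1) / tot[nz]
    out[m] = vals
    return CentralityVector("closeness", out, H.sample, H.timepoint,
                            {"harmonic": harmonic, "distance": distance})


def all_centralities(H: HiCMatrix, distance: str = "reciprocal"
                     ) -> dict[str, CentralityVector]:
    return {
        "degree": degree_centrality(H),
        "eigenvector": eigenvector_centrality(H),
        "betweenness": betweenness_centrality(H, distance=distance),
        "closeness": closeness_centrality(H, distance=distance),
    }
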