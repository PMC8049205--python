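"""Spectral (von Neumann) network entropy and its hypergraph generalization.

A weighted graph's Laplacian L = D - A, scaled to unit trace, is a density
matrix: its eigenvalues are non-negative and sum to one, so the Shannon
formula -sum lambda ln lambda applies directly. For k-uniform hypergraphs
built from multi-correlations of genomic loci, the same formula is evaluated
on the normalized singular values of the mode-1 unfolding of the Laplacian
tensor. Higher entropy = less organized chromatin structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import hic_norm
from .errors import ValidationError
from .genome_model import HiCMatrix
from .hic_norm import CorrelationMatrix

__all__ = ["SpectralDensity", "UniformHypergraph", "network_entropy",
           "multicorrelation", "build_hypergraph", "tensor_entropy"]

HYPERGRAPH_NODE_CAP = 64


@dataclass
class SpectralDensity:
    """Normalized non-negative spectrum (sums to 1) with provenance."""

    lambdas: np.ndarray
    source: str = ""
    degenerate: bool = False

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.min(initial=0.0) < -1e-12:
            raise ValidationError("spectrum has a significantly negative value")
        lam = np.clip(lam, 0.0, None)
        if not self.degenerate and abs(lam.sum() - 1.0) > 1e-10:
            raise ValidationError("normalized spectrum must sum to 1")
        self.lambdas = lam

    def entropy(self) -> float:
        lam = self.lambdas[self.lambdas > 0]
        return float(-(lam * np.log(lam)).sum()) if lam.size else 0.0


@dataclass
class UniformHypergraph:
    """Order-k supersymmetric weighted adjacency tensor on n nodes.

    Entries with repeated indices are zero; every edge weight lies in [0, 1]
    and is written to all k! index permutations.
    """

    k: int
    n: int
    adjacency: np.ndarray
    meta: dict = field(default_factory=dict)

    def degrees(self) -> np.ndarray:
        """Node degree = sum of weights of incident edges.

        Each incident edge contributes (k-1)! entries to the node's slice of
        the supersymmetric tensor, hence the division.
        """
        axes = tuple(range(1, self.k))
        return self.adjacency.sum(axis=axes) / _factorial(self.k - 1)


def _factorial(k: int) -> int:
    out = 1
    for i in range(2, k + 1):
        out *= i
    return out


def _density_spectrum(L: np.ndarray) -> tuple[np.ndarray, bool]:
    tr = np.trace(L)
    if tr <= 0:
        return np.zeros(L.shape[0]), True
    lam = np.linalg.eigvalsh(L / tr)
    return np.clip(lam, 0.0, None), False


def network_entropy(obj, convention: str = "laplacian"
                    ) -> tuple[SpectralDensity, float]:
    """Von Neumann entropy of a Hi-C-derived graph (natural log, nats).

    The adjacency is |off-diagonal correlation| for a correlation-matrix
    input, the balanced contact matrix for a contact-matrix input, or the
    array itself for a plain symmetric matrix. Default convention builds the
    unit-trace Laplacian density L/tr(L); ``convention='eigenvalues'``
    instead normalizes the eigenvalue magnitudes of the adjacency itself.
    """
    if isinstance(obj, CorrelationMatrix):
        m = obj.mask
        A = np.abs(obj.values[np.ix_(m, m)])
        np.fill_diagonal(A, 0.0)
        src = f"correlation:{obj.source}"
    elif isinstance(obj, HiCMatrix):
        B = obj if obj.meta.get("balance_converged") else hic_norm.balance(obj)
        m = obj.mask
        A = B.values[np.ix_(m, m)].copy()
        np.fill_diagonal(A, 0.0)
        src = f"contacts:{obj.sample}"
    else:
        A = np.asarray(obj, dtype=float).copy()
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("adjacency must be a square matrix")
        if np.abs(A - A.T).max(initial=0.0) > 1e-8:
            raise ValidationError("adjacency must be symmetric")
        np.fill_diagonal(A, 0.0)
        src = "matrix"
    if convention == "laplacian":
        L = np.diag(A.sum(axis=1)) - A
        lam, degenerate = _density_spectrum(L)
    elif convention == "eigenvalues":
        lam = np.abs(np.linalg.eigvalsh(A))
        tot = lam.sum()
        degenerate = tot == 0
        lam = lam / tot if tot > 0 else lam
    else:
        raise ValidationError(f"unknown entropy convention {convention!r}")
    dens = SpectralDensity(lam, source=src, degenerate=degenerate)
    return dens, dens.entropy()


def multicorrelation(C: CorrelationMatrix | np.ndarray, idx) -> float:
    """Joint linear dependence of the loci ``idx``: sqrt(1 - det R).

    R is the principal correlation submatrix on ``idx``. For two loci this is
    |r|; for R = I it is 0; the value is clipped to [0, 1].
    """
    idx = list(idx)
    if len(set(idx)) != len(idx):
        raise ValidationError("multicorrelation indices must be distinct")
    V = C.values if isinstance(C, CorrelationMatrix) else np.asarray(C, float)
    R = V[np.ix_(idx, idx)]
    det = float(np.linalg.det(R))
    if det > 1 + 1e-8:
        raise ValidationError(
            f"det(R) = {det} > 1: submatrix is not a valid correlation matrix")
    return float(np.clip(np.sqrt(max(1.0 - det, 0.0)), 0.0, 1.0))


def build_hypergraph(C: CorrelationMatrix, k: int, threshold: float = 0.0,
                     node_cap: int = HYPERGRAPH_NODE_CAP) -> UniformHypergraph:
    """k-uniform hypergraph on the unmasked loci via multi-correlations.

    Every k-subset with multi-correlation >= threshold becomes an edge of
    that weight (written to all k! symmetric tensor positions); k = 2 reduces
    to thresholded |C| with zero diagonal. Storage is O(n^k), so n after
    masking is capped (default 64; re-bin at coarser resolution for more).
    """
    if k not in (2, 3, 4):
        raise ValidationError("hypergraph order k must be 2, 3 or 4")
    m = C.mask
    sub = C.values[np.ix_(m, m)]
    n = sub.shape[0]
    if n > node_cap:
        raise ValidationError(
            f"{n} unmasked bins exceeds the n^{k} storage cap {node_cap}; "
            "re-bin the map at coarser resolution")
    A = np.zeros((n,) * k)
    for combo in itertools.combinations(range(n), k):
        w = multicorrelation(sub, combo)
        if w >= threshold and w > 0:
            for perm in itertools.permutations(combo):
                A[perm] = w
    return UniformHypergraph(k, n, A,
                             meta={"threshold": threshold, "source": C.source})


def tensor_entropy(G: UniformHypergraph) -> tuple[SpectralDensity, float]:
    """Entropy of a uniform hypergraph from its Laplacian tensor spectrum.

    L = D - A with node degrees on the super-diagonal; the generalized
    singular values are the singular values of the mode-1 unfolding
    (n x n^(k-1)), normalized to sum 1. For k = 2 this equals the network
    entropy of the same weighted graph.
    """
    n, k = G.n, G.k
    L = -G.adjacency.copy()
    deg = G.degrees()
    diag = tuple(np.arange(n) for _ in range(k))
    L[diag] += deg
    unfold = L.reshape(n, -1)
    sv = np.linalg.svd(unfold, compute_uv=False)
    tot = sv.sum()
    if tot == 0:
        dens = SpectralDensity(np.zeros(n), source="hypergraph",
                               degenerate=True)
        return dens, 0.0
    dens = SpectralDensity(sv / tot, source="hypergraph")
    return dens, dens.entropy()
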