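"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code with the package.
"""

import heapq

import numpy as np


def pairwise_pearson(X):
    """Textbook pairwise Pearson correlation between rows of X."""
    n = X.shape[0]
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            den = np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
            C[i, j] = (xi * xj).sum() / den if den > 0 else 0.0
    return C


def length_matrix(A):
    """Edge lengths 1/weight; 0 marks absent edges."""
    with np.errstate(divide="ignore"):
        return np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), 0.0)


def dijkstra_single_source(L, src):
    """Shortest-path distances from src on edge-length matrix L (0 = no edge)."""
    n = L.shape[0]
    dist = np.full(n, np.inf)
    dist[src] = 0.0
    heap = [(0.0, src)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in range(n):
            if L[u, v] > 0 and d + L[u, v] < dist[v]:
                dist[v] = d + L[u, v]
                heapq.heappush(heap, (dist[v], v))
    return dist


def closeness_oracle(A):
    """(n-1)/sum_j d(i,j); harmonic form if any pair is unreachable."""
    n = A.shape[0]
    L = length_matrix(A)
    D = np.vstack([dijkstra_single_source(L, s) for s in range(n)])
    np.fill_diagonal(D, 0.0)
    out = np.zeros(n)
    if np.isinf(D).any():
        for i in range(n):
            finite = np.isfinite(D[i]) & (D[i] > 0)
            out[i] = (1.0 / D[i][finite]).sum() / (n - 1)
    else:
        for i in range(n):
            tot = D[i].sum()
            out[i] = (n - 1) / tot if tot > 0 else 0.0
    return out


def betweenness_oracle(A, rtol=1e-9):
    """Floyd-Warshall all-pairs shortest-path counting betweenness.

    Normalized by (n-1)(n-2)/2. Assumes generic (tie-free) weights, which
    random continuous weights give almost surely.
    """
    n = A.shape[0]
    L = length_matrix(A)
    D = np.full((n, n), np.inf)
    cnt = np.zeros((n, n))
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(cnt, 1.0)
    for i in range(n):
        for j in range(n):
            if i != j and L[i, j] > 0:
                D[i, j] = L[i, j]
                cnt[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            if i == k:
                continue
            for j in range(n):
                if j == k or j == i:
                    continue
                nd = D[i, k] + D[k, j]
                if not np.isfinite(nd):
                    continue
                if nd < D[i, j] * (1 - rtol):
                    D[i, j] = nd
                    cnt[i, j] = cnt[i, k] * cnt[k, j]
                elif abs(nd - D[i, j]) <= rtol * nd:
                    cnt[i, j] += cnt[i, k] * cnt[k, j]
    bet = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or not np.isfinite(D[s, t]) or cnt[s, t] == 0:
                    continue
                via = D[s, v] + D[v, t]
                if np.isfinite(via) and abs(via - D[s, t]) <= rtol * max(D[s, t], 1e-300):
                    bet[v] += cnt[s, v] * cnt[v, t] / cnt[s, t]
    return bet / ((n - 1) * (n - 2) / 2.0)


def eigenvector_oracle(A):
    """Perron vector via full dense eigendecomposition."""
    w, V = np.linalg.eigh(A)
    v = np.abs(V[:, np.argmax(w)])
    return v / np.linalg.norm(v)


def lp_S_oracle(Z_list, n_obs):
    """Naive triple-loop version of the per-coefficient LP statistics."""
    k = len(Z_list)
    n = Z_list[0].shape[0]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            zbar = sum(Z[i, j] for Z in Z_list) / k
            S[i, j] = (n_obs - 3) * sum((Z[i, j] - zbar) ** 2 for Z in Z_list)
    return S


def binned_mean_oracle(mids, values, bin_starts, resolution, pseudocount=1.0):
    """Per-bin mean of log2(value+pseudocount) grouped by midpoint bin."""
    n = len(bin_starts)
    out = np.zeros(n)
    for b in range(n):
        lo = bin_starts[b]
        hi = lo + resolution
        sel = [np.log2(v + pseudocount) for m, v in zip(mids, values)
               if lo <= m < hi]
        if sel:
            out[b] = float(np.mean(sel))
    return out
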