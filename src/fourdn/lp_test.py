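"""Larntz-Perlman test for equality of k >= 2 correlation matrices.

Given sample correlation matrices C(1..k) each estimated from n_obs
observations, the null hypothesis is that all population correlation matrices
are equal. Each off-diagonal coefficient is Fisher z-transformed,
Z_ij = arctanh(C_ij); the per-coefficient statistic is

    S_ij = (n_obs - 3) * sum_m (Z_ij(m) - Zbar_ij)^2,

approximately chi-square with k-1 degrees of freedom under the null. The test
statistic T = max_{i<j} S_ij is referred to the chi-square quantile at the
Sidak-corrected level eps(alpha) = (1 - alpha)^(2/(n(n-1))), which controls
the familywise error over the n(n-1)/2 coefficients. The p-value inverts the
critical-value relation and is conservative (the true p-value can be smaller
when coefficients are correlated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import hic_norm
from .errors import AlignmentError, ValidationError
from .hic_norm import CorrelationMatrix

__all__ = ["LPInput", "LPResult", "fisher_z", "lp_statistics",
           "sidak_epsilon", "lp_test", "lp_on_hic"]

DEFAULT_CLIP = 1.0 - 1e-12


@dataclass
class LPInput:
    matrices: list                   # k arrays or CorrelationMatrix, n x n
    n_obs: int
    alpha: float = 0.05

    def arrays(self) -> list[np.ndarray]:
        out = []
        for M in self.matrices:
            V = M.values if isinstance(M, CorrelationMatrix) else np.asarray(M, float)
            out.append(V)
        return out

    def __post_init__(self):
        arrs = self.arrays()
        if len(arrs) < 2:
            raise ValidationError("LP test requires k >= 2 matrices")
        n = arrs[0].shape[0]
        for V in arrs:
            if V.shape != (n, n):
                raise AlignmentError("all correlation matrices must be n x n "
                                     "on a common bin set")
            if np.abs(V).max() > 1 + 1e-12:
                raise ValidationError("correlation entries must be in [-1,1]")
        if self.n_obs < 4:
            raise ValidationError(
                "n_obs must be >= 4: the Fisher-z variance factor is "
                "(n_obs - 3)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class LPResult:
    Z: list
    S: np.ndarray
    T: float
    argmax: tuple
    epsilon: float
    critical_value: float
    p_value: float
    reject: bool
    n: int
    k: int
    n_obs: int
    alpha: float
    clip_count: int = 0
    meta: dict = field(default_factory=dict)


def fisher_z(C, clip: float = DEFAULT_CLIP) -> np.ndarray:
    """Elementwise Fisher z-transform arctanh(C) on off-diagonal entries.

    |C_ij| is clipped at ``clip`` first so that perfect correlations (common
    in small toy matrices) stay finite; the diagonal is set to 0 and plays no
    role downstream.
    """
    V = C.values if isinstance(C, CorrelationMatrix) else np.asarray(C, float)
    V = np.clip(V, -clip, clip)
    Z = np.arctanh(V)
    np.fill_diagonal(Z, 0.0)
    return Z


def lp_statistics(Z_list: list[np.ndarray], n_obs: int
                  ) -> tuple[np.ndarray, float, tuple]:
    """Per-coefficient chi-square statistics S and the max statistic T.

    S_ij = (n_obs - 3) * sum_m (Z_ij(m) - Zbar_ij)^2 with the across-sample
    mean Zbar; T = max over i < j, argmax tie-broken to the lexicographically
    smallest (i, j).
    """
    if len(Z_list) < 2:
        raise ValidationError("LP statistics require k >= 2 matrices")
    if n_obs < 4:
        raise ValidationError("n_obs must be >= 4 for the (n_obs - 3) factor")
    Zs = np.stack([np.asarray(Z, float) for Z in Z_list])
    Zbar = Zs.mean(axis=0)
    S = (n_obs - 3) * ((Zs - Zbar) ** 2).sum(axis=0)
    np.fill_diagonal(S, 0.0)
    n = S.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = S[iu, ju]
    best = int(np.argmax(vals))      # first occurrence = smallest (i, j)
    return S, float(vals[best]), (int(iu[best]), int(ju[best]))


def sidak_epsilon(alpha: float, n: int) -> float:
    """Sidak-corrected per-comparison level over the n(n-1)/2 coefficients."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if n < 2:
        raise ValidationError("n must be >= 2")
    return float((1.0 - alpha) ** (2.0 / (n * (n - 1))))


def lp_test(inp: LPInput, clip: float = DEFAULT_CLIP) -> LPResult:
    """Run the full procedure and retain every intermediate object.

    Rejects when T exceeds the chi-square(k-1) quantile at probability
    eps(alpha); the conservative p-value is 1 - F(T)^(n(n-1)/2), the alpha
    that solves the critical-value equation.
    """
    arrs = inp.arrays()
    k = len(arrs)
    n = arrs[0].shape[0]
    clip_count = 0
    for V in arrs:
        off = ~np.eye(n, dtype=bool)
        clip_count += int((np.abs(V[off]) > clip).sum())
    Z = [fisher_z(V, clip=clip) for V in arrs]
    S, T, argmax = lp_statistics(Z, inp.n_obs)
    eps = sidak_epsilon(inp.alpha, n)
    crit = float(stats.chi2.ppf(eps, df=k - 1))
    m_pairs = n * (n - 1) / 2.0
    p = float(1.0 - stats.chi2.cdf(T, df=k - 1) ** m_pairs)
    return LPResult(Z=Z, S=S, T=T, argmax=argmax, epsilon=eps,
                    critical_value=crit, p_value=p, reject=bool(T > crit),
                    n=n, k=k, n_obs=inp.n_obs, alpha=inp.alpha,
                    clip_count=clip_count)


def lp_on_hic(H_list, region: tuple[int, int] | None = None,
              alpha: float = 0.05, log_transform: bool = True,
              observed_expected: bool = True) -> LPResult:
    """Compare Hi-C samples over a bin range via their correlation matrices.

    Region submatrices are masked jointly (intersection of per-sample masks),
    turned into contact-profile correlation matrices by the default pipeline,
    and tested; n_obs is the number of jointly unmasked bins in the region.
    ``argmax`` in the result is reported in region-local unmasked coordinates
    with the original bin ids in ``meta['argmax_bins']``.
    """
    from .feature_analyzer import shared_mask

    if len(H_list) < 2:
        raise ValidationError("LP test requires k >= 2 Hi-C samples")
    n_bins = H_list[0].n_bins
    lo, hi = (0, n_bins) if region is None else region
    if not (0 <= lo < hi <= n_bins):
        raise ValidationError(f"region ({lo}, {hi}) out of bounds")
    subs = [H.submatrix(lo, hi) for H in H_list]
    joint = shared_mask(subs)
    if joint.sum() < 4:
        raise ValidationError("region has fewer than 4 jointly unmasked bins")
    mats = []
    for H in subs:
        v = H.values.copy()
        v[~joint, :] = 0.0
        v[:, ~joint] = 0.0
        Hm = H.with_values(v)
        C = hic_norm.correlation_matrix(
            Hm, log_transform=log_transform,
            observed_expected=observed_expected)
        mats.append(C.values[np.ix_(joint, joint)])
    n_obs = int(joint.sum())
    res = lp_test(LPInput(mats, n_obs=n_obs, alpha=alpha))
    ids = np.where(joint)[0] + lo
    res.meta["argmax_bins"] = (int(ids[res.argmax[0]]), int(ids[res.argmax[1]]))
    res.meta["region"] = (int(lo), int(hi))
    return res
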