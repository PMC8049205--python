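"""Contact-map conditioning: matrix balancing, observed/expected, correlation.

The default pipeline feeding compartment calls, entropy and the LP test is
balance -> observed/expected -> log2(x+1) -> row-wise Pearson correlation.
Every step is individually switchable because published Hi-C workflows differ
on which conditioning precedes correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genome_model import HiCMatrix

__all__ = ["CorrelationMatrix", "balance", "observed_over_expected",
           "correlation_matrix"]


@dataclass
class CorrelationMatrix:
    """Pearson correlation of contact profiles; masked bins zeroed out."""

    values: np.ndarray
    mask: np.ndarray
    n_obs: int
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.abs(v).max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("correlation entries must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def balance(H: HiCMatrix, tol: float = 1e-6, max_iter: int = 200) -> HiCMatrix:
    """Iterative proportional fitting (square-root variant).

    Repeatedly divides by the square root of the row-sum vector until all
    unmasked row sums agree within ``tol`` times their mean. Masked rows stay
    zero. On non-convergence the last iterate is returned with
    ``meta['balance_converged'] = False`` and a warning.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    A = H.values.copy()
    m = H.mask
    if not m.any():
        return H.with_values(A, balance_converged=True)
    converged = False
    for _ in range(max_iter):
        s = A[np.ix_(m, m)].sum(axis=1)
        mu = s.mean()
        if mu == 0:
            break
        if np.abs(s - mu).max() <= tol * mu:
            converged = True
            break
        d = np.sqrt(s / mu)
        d[d == 0] = 1.0
        A[np.ix_(m, m)] /= np.outer(d, d)
    else:
        s = A[np.ix_(m, m)].sum(axis=1)
        mu = s.mean()
        converged = bool(mu > 0 and np.abs(s - mu).max() <= tol * mu)
    if not converged:
        warnings.warn(f"balancing did not converge in {max_iter} iterations",
                      stacklevel=2)
    return H.with_values(A, balance_converged=converged)


def observed_over_expected(H: HiCMatrix) -> HiCMatrix:
    """Divide each entry by the mean of its |i-j| diagonal stratum.

    Stratum means are computed over unmasked bin pairs only; strata whose mean
    is zero map to zero.
    """
    n = H.n_bins
    A = H.values
    m = H.mask.astype(float)
    valid = np.outer(m, m)
    out = np.zeros_like(A)
    idx = np.arange(n)
    offset = np.abs(idx[:, None] - idx[None, :])
    # per-stratum sums over unmasked pairs
    sums = np.bincount(offset.ravel(), weights=(A * valid).ravel(), minlength=n)
    cnts = np.bincount(offset.ravel(), weights=valid.ravel(), minlength=n)
    means = np.divide(sums, cnts, out=np.zeros(n), where=cnts > 0)
    expected = means[offset]
    np.divide(A, expected, out=out, where=expected > 0)
    out *= valid
    return H.with_values(out, oe=True)


def correlation_matrix(H: HiCMatrix, log_transform: bool = True,
                       observed_expected: bool = True) -> CorrelationMatrix:
    """Pearson correlation between contact-profile rows.

    Each unmasked locus is described by its row of the (optionally
    observed/expected, optionally log2(x+1)) matrix restricted to unmasked
    columns; ``n_obs`` is the number of unmasked bins. Constant rows get
    correlation 0 and are counted in ``meta['constant_rows']``.
    """
    m = H.mask
    n_obs = int(m.sum())
    if n_obs < 4:
        raise ValidationError(
            "correlation matrix requires >= 4 unmasked bins "
            "(the LP test needs n_obs - 3 > 0)")
    M = observed_over_expected(H) if observed_expected else H
    X = M.values[np.ix_(m, m)]
    if log_transform:
        X = np.log2(X + 1.0)
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc ** 2).sum(axis=1))
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    Z = Xc / sd_safe[:, None]
    C = Z @ Z.T
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, np.where(constant, 0.0, 1.0))
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    full = np.zeros((H.n_bins, H.n_bins))
    full[np.ix_(m, m)] = C
    return CorrelationMatrix(full, mask=m, n_obs=n_obs, source=H.sample,
                             meta={"constant_rows": int(constant.sum()),
                                   "log_transform": log_transform,
                                   "observed_expected": observed_expected})
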