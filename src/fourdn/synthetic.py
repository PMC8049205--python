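"""Seeded generators of Hi-C maps, expression tracks and time-series fixtures.

The simulated world is a single chromosome with megabase-scale alternating
A/B compartment blocks: expected contacts decay with genomic distance as a
power law (1+|i-j|)^(-alpha) with the canonical exponent alpha = 1, are
enriched by a factor (1 + gamma) within a compartment, scaled to a total
sequencing depth, and Poisson-sampled. Expression is higher in A than in B
by a fixed log2 effect plus Gaussian noise. Time series plant progressive
compartment flips and expression shifts at chosen loci, emulating
differentiation/reprogramming experiments.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_model import (BinIndex, ExpressionTrack, GeneTable, HiCMatrix,
                           SampleSheet, bin_expression, write_hic_dense)

__all__ = ["SimConfig", "simulate_hic", "simulate_expression",
           "simulate_timeseries", "simulate_correlation_samples"]


@dataclass
class SimConfig:
    """Parameters of the simulated chromosome.

    Defaults mirror a 20 Mb chromosome arm at 100 kb resolution with eight
    alternating compartment blocks, a strong compartment signal (gamma = 2)
    and the canonical distance-decay exponent alpha = 1.
    """

    n_bins: int = 200
    resolution: int = 100_000
    chromosome: str = "chrS"
    decay_alpha: float = 1.0
    block_size: int = 25
    gamma: float = 2.0
    depth: float = 5e5
    expression_effect: float = 2.0   # log2 A-vs-B difference
    expression_sd: float = 0.5
    changed_loci: tuple = ()
    change_expression_effect: float = 4.0   # log2 shift at final timepoint
    change_structure_frac: float = 1.0      # compartment-flip completion
    seed: int = 0

    def labels(self) -> np.ndarray:
        """Planted compartment membership: True = A."""
        return (np.arange(self.n_bins) // self.block_size) % 2 == 0

    def bins(self) -> BinIndex:
        return BinIndex.from_range(self.chromosome, self.resolution,
                                   self.n_bins)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["changed_loci"] = list(d["changed_loci"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["changed_loci"] = tuple(d.get("changed_loci", ()))
        return cls(**d)


def _expected_matrix(cfg: SimConfig, a_membership: np.ndarray) -> np.ndarray:
    """Depth-scaled expected contacts for (possibly fractional) A membership."""
    n = cfg.n_bins
    idx = np.arange(n)
    base = (1.0 + np.abs(idx[:, None] - idx[None, :])) ** (-cfg.decay_alpha)
    a = np.asarray(a_membership, dtype=float)
    same = np.outer(a, a) + np.outer(1 - a, 1 - a)
    E = base * (1.0 + cfg.gamma * same)
    tot = np.triu(E).sum()
    return E * (cfg.depth / tot)


def _a_membership(cfg: SimConfig, t_frac: float = 0.0) -> np.ndarray:
    a = cfg.labels().astype(float)
    for i in cfg.changed_loci:
        target = 1.0 - a[i]
        a[i] = a[i] + (target - a[i]) * cfg.change_structure_frac * t_frac
    return a


def simulate_hic(cfg: SimConfig, t_frac: float = 0.0,
                 sample: str = "sim", timepoint: float = 0.0) -> HiCMatrix:
    """Poisson-sampled contact matrix; bitwise-reproducible for a fixed cfg.

    ``t_frac`` in [0, 1] moves the planted changed loci toward their flipped
    compartment (0 at the first time point, 1 at the last).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1, int(round(t_frac * 1000))]))
    E = _expected_matrix(cfg, _a_membership(cfg, t_frac))
    n = cfg.n_bins
    upper = rng.poisson(np.triu(E))
    counts = np.triu(upper) + np.triu(upper, 1).T
    return HiCMatrix(cfg.bins(), counts.astype(float), sample=sample,
                     timepoint=timepoint)


def simulate_expression(cfg: SimConfig, t_frac: float = 0.0,
                        sample: str = "sim",
                        timepoint: float = 0.0) -> ExpressionTrack:
    """Per-bin log2 expression: A/B effect + noise + planted shifts.

    The raw log2 signal is exponentiated to a TPM-like scale and re-logged
    through the standard log2(x+1) pipeline, matching what binned real data
    goes through.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [cfg.seed, 2, int(round(t_frac * 1000))]))
    labels = cfg.labels()
    raw = cfg.expression_effect * labels.astype(float)
    raw = raw + rng.normal(0.0, cfg.expression_sd, size=cfg.n_bins)
    for i in cfg.changed_loci:
        raw[i] += cfg.change_expression_effect * t_frac
    tpm = np.exp2(raw)
    values = np.log2(tpm + 1.0)
    return ExpressionTrack(cfg.bins(), values, unit="TPM", sample=sample,
                           timepoint=timepoint)


def _gene_table(cfg: SimConfig, tracks: dict[str, np.ndarray]) -> GeneTable:
    """One gene per bin, centered in the bin, with TPM columns per timepoint."""
    bins = cfg.bins()
    df = pd.DataFrame({
        "symbol": [f"GENE{i:04d}" for i in range(cfg.n_bins)],
        "chrom": cfg.chromosome,
        "start": bins.starts + cfg.resolution // 4,
        "end": bins.starts + 3 * cfg.resolution // 4,
    })
    for col, vals in tracks.items():
        df[col] = vals
    return GeneTable(df)


def simulate_timeseries(cfg: SimConfig, T: int = 3,
                        outdir: str | os.PathLike | None = None,
                        sample: str = "sim") -> tuple:
    """Coupled Hi-C/expression series with progressive planted changes.

    Returns ``(sheet, hic_list, expr_list, genes)``. When ``outdir`` is
    given, matrices (TSV), a gene-level expression table, the sample sheet
    CSV and the config JSON are written there, reloadable by the standard
    readers.
    """
    if T < 1:
        raise ValidationError("need at least one timepoint")
    fracs = [0.0] if T == 1 else [t / (T - 1) for t in range(T)]
    hics, exprs, tpm_cols = [], [], {}
    for t, f in enumerate(fracs):
        hics.append(simulate_hic(cfg, t_frac=f, sample=sample, timepoint=t))
        e = simulate_expression(cfg, t_frac=f, sample=sample, timepoint=t)
        exprs.append(e)
        tpm_cols[f"{sample}_{t}"] = np.exp2(e.values) - 1.0
    genes = _gene_table(cfg, tpm_cols)
    rows = []
    if outdir is not None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        expr_path = os.path.join(outdir, "expression.tsv")
        genes.df.to_csv(expr_path, sep="\t", index=False)
        cfg.to_json(os.path.join(outdir, "sim_config.json"))
        for t, H in enumerate(hics):
            hp = os.path.join(outdir, f"hic_t{t}.tsv")
            write_hic_dense(H, hp)
            rows.append((sample, t, hp, expr_path))
        sheet = SampleSheet(pd.DataFrame(
            rows, columns=["sample", "timepoint", "hic_path", "rnaseq_path"]))
        sheet.df.to_csv(os.path.join(outdir, "samples.csv"), index=False)
    else:
        sheet = SampleSheet(pd.DataFrame(
            [(sample, t, "", "") for t in range(T)],
            columns=["sample", "timepoint", "hic_path", "rnaseq_path"]))
    return sheet, hics, exprs, genes


def _psd_project(Sigma: np.ndarray) -> np.ndarray:
    """Nearest-PSD repair by eigenvalue clipping, unit diagonal restored."""
    w, V = np.linalg.eigh((Sigma + Sigma.T) / 2)
    w = np.clip(w, 1e-10, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def simulate_correlation_samples(Sigma: np.ndarray, n_obs: int, k: int,
                                 perturbation: dict | None = None,
                                 seed: int = 0) -> list[np.ndarray]:
    """k sample correlation matrices of multivariate-normal draws.

    ``perturbation`` (optional) is ``{"samples": [...], "block": (i0, i1),
    "delta": x}``: for the flagged samples, ``delta`` is added to the
    off-diagonal population correlations inside the block, with a PSD repair.
    Used to build null (no perturbation) and alternative LP-test scenarios.
    """
    if k < 2:
        raise ValidationError("LP machinery needs k >= 2 samples")
    Sigma = np.asarray(Sigma, dtype=float)
    n = Sigma.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    chol_null = np.linalg.cholesky(_psd_project(Sigma))
    chol_alt = None
    flagged = set()
    if perturbation is not None:
        flagged = set(perturbation.get("samples", [k - 1]))
        i0, i1 = perturbation["block"]
        P = Sigma.copy()
        blk = P[i0:i1, i0:i1] + perturbation["delta"]
        np.fill_diagonal(blk, 1.0)
        P[i0:i1, i0:i1] = np.clip(blk, -0.99, 0.99)
        np.fill_diagonal(P, 1.0)
        chol_alt = np.linalg.cholesky(_psd_project(P))
    out = []
    for m in range(k):
        L = chol_alt if m in flagged else chol_null
        X = rng.standard_normal((n_obs, n)) @ L.T
        out.append(np.corrcoef(X, rowvar=False))
    return out
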