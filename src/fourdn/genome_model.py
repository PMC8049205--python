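"""Core data types and I/O for binned Hi-C maps, expression tables and sample sheets.

Coordinates are 0-based half-open throughout (BED convention on output).
A :class:`BinIndex` ties a contact matrix and an expression track to the same
uniform binning of one chromosome, so downstream feature matrices stay aligned.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

SYMMETRY_RTOL = 1e-6

__all__ = [
    "BinIndex",
    "HiCMatrix",
    "ExpressionTrack",
    "GeneTable",
    "SampleSheet",
    "load_sample_sheet",
    "load_hic_dense",
    "write_hic_dense",
    "load_gene_table",
    "bin_expression",
]


@dataclass(frozen=True)
class BinIndex:
    """Uniform binning of one chromosome.

    ``starts`` are 0-based half-open bin start coordinates with constant step
    equal to ``resolution``.
    """

    chromosome: str
    resolution: int
    starts: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        if self.resolution <= 0:
            raise ValidationError("resolution must be a positive integer")
        if starts.ndim != 1 or starts.size == 0:
            raise ValidationError("starts must be a non-empty 1-D array")
        if starts.size > 1:
            step = np.diff(starts)
            if not np.all(step == self.resolution):
                raise ValidationError(
                    "bin starts must increase with constant step = resolution"
                )

    @property
    def n_bins(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.resolution

    @classmethod
    def from_range(cls, chromosome: str, resolution: int, n_bins: int,
                   start: int = 0) -> "BinIndex":
        starts = start + resolution * np.arange(n_bins, dtype=np.int64)
        return cls(chromosome, resolution, starts)

    def locate(self, position: int) -> int:
        """Bin holding ``position``; -1 if outside the indexed range."""
        i = (position - int(self.starts[0])) // self.resolution
        return int(i) if 0 <= i < self.n_bins else -1

    def __eq__(self, other) -> bool:
        return (isinstance(other, BinIndex)
                and self.chromosome == other.chromosome
                and self.resolution == other.resolution
                and np.array_equal(self.starts, other.starts))

    def __hash__(self):
        return hash((self.chromosome, self.resolution,
                     int(self.starts[0]), self.n_bins))


def _mask_from_values(values: np.ndarray) -> np.ndarray:
    return values.sum(axis=1) > 0


@dataclass
class HiCMatrix:
    """Symmetric non-negative contact matrix bound to a bin index.

    ``mask`` marks valid bins; rows/columns of masked-out bins are zero.
    ``meta`` carries processing provenance (balancing convergence, ...).
    """

    bins: BinIndex
    values: np.ndarray
    sample: str = ""
    timepoint: float = 0.0
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError(f"contact matrix must be square, got {v.shape}")
        if v.shape[0] != self.bins.n_bins:
            raise AlignmentError(
                f"matrix size {v.shape[0]} != bin count {self.bins.n_bins}")
        if np.any(v < 0):
            raise FormatError("contact matrix has negative entries")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > 1e-8 * scale:
            raise FormatError("contact matrix is not symmetric within 1e-8")
        self.values = v
        if self.mask is None:
            self.mask = _mask_from_values(v)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.size != v.shape[0]:
                raise AlignmentError("mask length does not match matrix size")
        # masked-out rows/columns must be zero
        off = ~self.mask
        if np.any(v[off, :] != 0) or np.any(v[:, off] != 0):
            raise ValidationError("masked-out rows/columns must be all zero")

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def with_values(self, values: np.ndarray, **meta) -> "HiCMatrix":
        """Copy carrying new values (mask recomputed) and merged metadata."""
        return HiCMatrix(self.bins, values, self.sample, self.timepoint,
                         None, {**self.meta, **meta})

    def submatrix(self, lo: int, hi: int) -> "HiCMatrix":
        """Contiguous bin range [lo, hi) as a new HiCMatrix."""
        sub_bins = BinIndex(self.bins.chromosome, self.bins.resolution,
                            self.bins.starts[lo:hi])
        return HiCMatrix(sub_bins, self.values[lo:hi, lo:hi], self.sample,
                         self.timepoint, None, dict(self.meta))


@dataclass
class ExpressionTrack:
    """Per-bin log2 expression aligned to a BinIndex."""

    bins: BinIndex
    values: np.ndarray
    unit: str = "TPM"
    sample: str = ""
    timepoint: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.bins.n_bins:
            raise AlignmentError("expression track length must equal n_bins")
        if not np.all(np.isfinite(v)):
            raise ValidationError("expression track must be finite everywhere")
        if self.unit not in ("TPM", "RPKM"):
            raise ValidationError("unit must be TPM or RPKM")
        self.values = v


@dataclass
class GeneTable:
    """Gene records: symbol, chromosome, 0-based half-open coordinates, and
    one expression column per sample/timepoint."""

    df: pd.DataFrame

    REQUIRED = ("symbol", "chrom", "start", "end")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValidationError(f"gene table missing column '{col}'")
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValidationError("gene table requires start < end")

    @property
    def value_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.REQUIRED]

    def on_chromosome(self, chromosome: str) -> "GeneTable":
        return GeneTable(self.df[self.df["chrom"] == chromosome].reset_index(drop=True))


@dataclass
class SampleSheet:
    """Experiment metadata: one row per (sample, timepoint) with data paths."""

    df: pd.DataFrame

    REQUIRED = ("sample", "timepoint", "hic_path", "rnaseq_path")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValidationError(f"sample sheet missing column '{col}'")
        keys = list(zip(self.df["sample"], self.df["timepoint"]))
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (sample, timepoint) rows in sample sheet")
        self.df = self.df.sort_values("timepoint", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def rows(self):
        return self.df.itertuples(index=False)


def load_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read the experiment metadata CSV (sample,timepoint,hic_path,rnaseq_path).

    Relative data paths are resolved against the sheet's directory; their
    existence is checked lazily by the loaders that consume them.
    """
    df = pd.read_csv(path)
    sheet = SampleSheet(df)
    base = os.path.dirname(os.path.abspath(os.fspath(path)))
    for col in ("hic_path", "rnaseq_path"):
        sheet.df[col] = [
            p if os.path.isabs(str(p)) else os.path.join(base, str(p))
            for p in sheet.df[col]
        ]
    return sheet


def _load_cool(path: str, resolution: int, chromosome: str) -> np.ndarray:
    """Dense intra-chromosomal matrix from a cooler-schema HDF5 container.

    Supports single-resolution ``.cool`` files and multi-resolution ``.mcool``
    (group ``resolutions/<res>``). Read-only; bin weights are ignored.
    """
    import h5py

    with h5py.File(path, "r") as f:
        grp = f
        if "bins" not in f:
            key = f"resolutions/{resolution}"
            if key not in f:
                raise FormatError(
                    f"no resolution {resolution} group in cooler file {path}")
            grp = f[key]
        chrom_names = [c.decode() if isinstance(c, bytes) else str(c)
                       for c in grp["chroms/name"][:]]
        if chromosome not in chrom_names:
            raise FormatError(f"chromosome {chromosome} not in cooler file")
        cid = chrom_names.index(chromosome)
        bin_chrom = grp["bins/chrom"][:]
        sel = np.where(bin_chrom == cid)[0]
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        n = hi - lo
        b1 = grp["pixels/bin1_id"][:]
        b2 = grp["pixels/bin2_id"][:]
        cnt = grp["pixels/count"][:].astype(float)
        keep = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        mat = np.zeros((n, n))
        i, j = b1[keep] - lo, b2[keep] - lo
        mat[i, j] = cnt[keep]
        mat[j, i] = cnt[keep]
        return mat


def load_hic_dense(path: str | os.PathLike, resolution: int, chromosome: str,
                   sample: str = "", timepoint: float = 0.0,
                   start: int = 0) -> HiCMatrix:
    """Load a dense intra-chromosomal contact matrix.

    Text input is a whitespace/tab-delimited numeric n x n block; ``.cool`` /
    ``.mcool`` containers are read through their HDF5 schema. Matrices that are
    symmetric within a relative 1e-6 are symmetrized by averaging; larger
    asymmetry is a format error (never silently fixed).
    """
    p = os.fspath(path)
    if p.endswith((".cool", ".mcool")):
        v = _load_cool(p, resolution, chromosome)
    else:
        v = np.loadtxt(p, ndmin=2)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise FormatError(f"expected a square matrix in {p}, got {v.shape}")
    if np.any(v < 0):
        raise FormatError(f"negative contact counts in {p}")
    scale = max(np.abs(v).max(), 1.0)
    asym = np.abs(v - v.T).max() / scale
    if asym > SYMMETRY_RTOL:
        raise FormatError(
            f"matrix in {p} asymmetric (relative deviation {asym:.2e} > 1e-6)")
    v = (v + v.T) / 2.0
    bins = BinIndex.from_range(chromosome, resolution, v.shape[0], start=start)
    mask = _mask_from_values(v)
    v = v.copy()
    v[~mask, :] = 0.0
    v[:, ~mask] = 0.0
    return HiCMatrix(bins, v, sample=sample, timepoint=timepoint, mask=mask)


def write_hic_dense(H: HiCMatrix, path: str | os.PathLike) -> None:
    """Write the dense matrix as TSV (full precision round-trip)."""
    np.savetxt(path, H.values, delimiter="\t", fmt="%.17g")


def load_gene_table(path: str | os.PathLike) -> GeneTable:
    """Read a gene expression TSV: symbol, chrom, start, end, then one value
    column per sample_timepoint."""
    df = pd.read_csv(path, sep="\t")
    return GeneTable(df)


def bin_expression(genes: GeneTable, bins: BinIndex, column: str | None = None,
                   pseudocount: float = 1.0, mean_then_log: bool = False,
                   unit: str = "TPM", sample: str = "",
                   timepoint: float = 0.0) -> ExpressionTrack:
    """Aggregate gene-level expression into per-bin log2 values.

    Each gene is assigned to the bin containing its midpoint (bins half-open).
    Default order of operations is log2(value + pseudocount) per gene, then the
    mean over genes in the bin; ``mean_then_log`` averages raw values first.
    Bins without genes get 0.

    Parameters
    ----------
    column
        Which expression column of the gene table to use; defaults to the
        single value column if unambiguous.
    pseudocount
        Added before the log2 transform; must be positive.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    out = np.zeros(bins.n_bins)
    df = genes.df
    if len(df) == 0:
        return ExpressionTrack(bins, out, unit=unit, sample=sample,
                               timepoint=timepoint)
    if column is None:
        cols = genes.value_columns
        if len(cols) != 1:
            raise ValidationError(
                f"ambiguous expression column; choose one of {cols}")
        column = cols[0]
    chroms = df["chrom"].unique()
    if not all(c == bins.chromosome for c in chroms):
        raise AlignmentError(
            f"gene table chromosomes {list(chroms)} != bin chromosome "
            f"{bins.chromosome}")
    mid = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    idx = (mid - int(bins.starts[0])) // bins.resolution
    ok = (idx >= 0) & (idx < bins.n_bins)
    idx = idx[ok]
    vals = df[column].to_numpy(dtype=float)[ok]
    if mean_then_log:
        sums = np.bincount(idx, weights=vals, minlength=bins.n_bins)
        cnts = np.bincount(idx, minlength=bins.n_bins)
        nz = cnts > 0
        out[nz] = np.log2(sums[nz] / cnts[nz] + pseudocount)
    else:
        logged = np.log2(vals + pseudocount)
        sums = np.bincount(idx, weights=logged, minlength=bins.n_bins)
        cnts = np.bincount(idx, minlength=bins.n_bins)
        nz = cnts > 0
        out[nz] = sums[nz] / cnts[nz]
    return ExpressionTrack(bins, out, unit=unit, sample=sample,
                           timepoint=timepoint)
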