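"""Structure-function feature matrices, change ranking, and gene reports.

For each time point a locus is described by five features: the four weighted
network centralities of its Hi-C contact profile (degree, eigenvector,
betweenness, closeness) plus its log2 expression. Columns are z-scored
jointly over all time points, so between-time-point shifts survive the
normalization, and loci are ranked by the path length their normalized
feature row traces through time.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import centrality as _centrality
from . import dimred, hic_norm
from .errors import AlignmentError, ValidationError
from .genome_model import BinIndex, ExpressionTrack, GeneTable, HiCMatrix

__all__ = ["FeatureMatrix", "ChangeRanking", "GeneReport", "FEATURE_COLUMNS",
           "build_feature_matrix", "first_principal_component",
           "normalize_features", "rank_changes", "gene_report",
           "shared_mask"]

FEATURE_COLUMNS = ("b_deg", "b_eig", "b_bet", "b_close", "r")

NCBI_URL = "https://www.ncbi.nlm.nih.gov/gene/?term={symbol}"
GENECARDS_URL = "https://www.genecards.org/cgi-bin/carddisp.pl?gene={symbol}"


@dataclass
class FeatureMatrix:
    """n x 5 structure-function matrix restricted to shared unmasked bins."""

    values: np.ndarray
    bins: BinIndex
    bin_ids: np.ndarray              # original bin indices of the rows
    timepoint: float = 0.0
    sample: str = ""
    columns: tuple = FEATURE_COLUMNS
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.bin_ids = np.asarray(self.bin_ids, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValidationError(
                f"feature matrix must have {len(self.columns)} columns")
        if self.values.shape[0] != self.bin_ids.size:
            raise AlignmentError("row count must equal number of bin ids")


@dataclass
class ChangeRanking:
    """Per-locus structure-function change scores with a top-k short list."""

    bin_ids: np.ndarray
    scores: np.ndarray               # aligned to bin_ids, >= 0
    order: np.ndarray                # indices into bin_ids, descending score
    bins: BinIndex
    top_k: int = 10

    @property
    def top_bin_ids(self) -> np.ndarray:
        return self.bin_ids[self.order[:self.top_k]]

    def to_frame(self) -> pd.DataFrame:
        b = self.bins
        ids = self.bin_ids[self.order]
        return pd.DataFrame({
            "rank": np.arange(1, ids.size + 1),
            "chrom": b.chromosome,
            "start": b.starts[ids],
            "end": b.starts[ids] + b.resolution,
            "bin": ids,
            "score": self.scores[self.order],
        })


@dataclass
class GeneReport:
    records: pd.DataFrame            # locus, score, genes, urls

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def to_html(self, path) -> None:
        rows = []
        for rec in self.records.itertuples(index=False):
            links = []
            for sym in str(rec.genes).split(",") if rec.genes else []:
                sym = sym.strip()
                if not sym:
                    continue
                links.append(
                    f'{_html.escape(sym)} '
                    f'[<a href="{NCBI_URL.format(symbol=sym)}">NCBI</a>] '
                    f'[<a href="{GENECARDS_URL.format(symbol=sym)}">GeneCards</a>]')
            rows.append(
                f"<tr><td>{rec.chrom}:{rec.start}-{rec.end}</td>"
                f"<td>{rec.score:.4g}</td><td>{'; '.join(links)}</td></tr>")
        doc = ("<html><body><table border='1'>"
               "<tr><th>locus</th><th>change score</th><th>genes</th></tr>"
               + "".join(rows) + "</table></body></html>")
        with open(path, "w") as fh:
            fh.write(doc)


def shared_mask(objects) -> np.ndarray:
    """Intersection of bin masks so feature rows align across time points."""
    masks = [np.asarray(o.mask, dtype=bool) for o in objects]
    out = masks[0].copy()
    for m in masks[1:]:
        if m.size != out.size:
            raise AlignmentError("cannot intersect masks of different lengths")
        out &= m
    return out


def build_feature_matrix(H: HiCMatrix, r: ExpressionTrack,
                         mask: np.ndarray | None = None,
                         distance: str = "reciprocal") -> FeatureMatrix:
    """Assemble [b_deg, b_eig, b_bet, b_close, r] for one time point.

    ``mask`` (default: H's own mask) selects the bin rows kept, typically the
    intersection of masks across all time points.
    """
    if H.bins != r.bins:
        raise AlignmentError("Hi-C matrix and expression track bins differ")
    cen = _centrality.all_centralities(H, distance=distance)
    m = H.mask if mask is None else np.asarray(mask, dtype=bool)
    ids = np.where(m)[0]
    cols = [cen["degree"].values[m], cen["eigenvector"].values[m],
            cen["betweenness"].values[m], cen["closeness"].values[m],
            r.values[m]]
    return FeatureMatrix(np.column_stack(cols), H.bins, ids,
                         timepoint=H.timepoint, sample=H.sample)


def first_principal_component(H: HiCMatrix) -> np.ndarray:
    """PC1 scores of the bins, from the correlation of the O/E-transformed map.

    Returns a full-length vector (masked bins 0). A degenerate (zero-variance)
    correlation matrix yields the zero vector with a warning.
    """
    import warnings

    C = hic_norm.correlation_matrix(H)
    m = C.mask
    sub = C.values[np.ix_(m, m)]
    if np.allclose(sub - sub.mean(axis=0, keepdims=True), 0.0):
        warnings.warn("degenerate correlation matrix; PC1 set to zero",
                      stacklevel=2)
        return np.zeros(H.n_bins)
    scores = dimred.pca(sub, d=1)[:, 0]
    out = np.zeros(H.n_bins)
    out[m] = scores
    return out


def normalize_features(stack: list[FeatureMatrix]) -> list[FeatureMatrix]:
    """Joint z-score of each feature column over all time points.

    Means and standard deviations are computed on the row-concatenation of the
    whole stack so that the same affine map applies at every time point;
    zero-variance columns map to zero.
    """
    if not stack:
        raise ValidationError("empty feature-matrix stack")
    shapes = {f.values.shape for f in stack}
    if len(shapes) > 1:
        raise AlignmentError("feature matrices in a stack must share a shape")
    X = np.vstack([f.values for f in stack])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = []
    for f in stack:
        Z = (f.values - mu) / sd_safe
        Z[:, sd == 0] = 0.0
        out.append(FeatureMatrix(Z, f.bins, f.bin_ids, f.timepoint, f.sample,
                                 f.columns, {**f.meta, "normalized": True}))
    return out


def rank_changes(stack: list[FeatureMatrix], top_k: int = 10) -> ChangeRanking:
    """Rank loci by total structure-function change across time.

    The score of a locus is the Euclidean path length of its normalized
    5-feature row through the ordered time points (sum of consecutive
    between-time-point distances). Identical trajectories score 0.
    """
    if len(stack) < 2:
        raise ValidationError("change ranking requires >= 2 timepoints")
    order = np.argsort([f.timepoint for f in stack], kind="stable")
    mats = [stack[i].values for i in order]
    ids = stack[order[0]].bin_ids
    for i in order:
        if not np.array_equal(stack[i].bin_ids, ids):
            raise AlignmentError("feature matrices must share bin ids")
    scores = np.zeros(mats[0].shape[0])
    for a, b in zip(mats[:-1], mats[1:]):
        scores += np.linalg.norm(b - a, axis=1)
    rank_order = np.argsort(-scores, kind="stable")
    return ChangeRanking(ids, scores, rank_order, stack[order[0]].bins,
                         top_k=top_k)


def gene_report(ranking: ChangeRanking, genes: GeneTable,
                top_k: int | None = None) -> GeneReport:
    """List genes overlapping each top-ranked locus with database links.

    URLs are built from fixed templates (NCBI gene query, GeneCards card);
    no network access happens. Loci without genes get an empty gene list.
    """
    k = ranking.top_k if top_k is None else top_k
    b = ranking.bins
    df = genes.on_chromosome(b.chromosome).df
    gs = df["start"].to_numpy() if len(df) else np.empty(0, dtype=int)
    ge = df["end"].to_numpy() if len(df) else np.empty(0, dtype=int)
    rows = []
    for rank, idx in enumerate(ranking.order[:k], start=1):
        bid = int(ranking.bin_ids[idx])
        lo = int(b.starts[bid])
        hi = lo + b.resolution
        hit = (gs < hi) & (ge > lo)
        syms = sorted(df["symbol"][hit]) if len(df) else []
        rows.append({
            "rank": rank,
            "chrom": b.chromosome,
            "start": lo,
            "end": hi,
            "score": float(ranking.scores[idx]),
            "genes": ",".join(syms),
            "ncbi_urls": ";".join(NCBI_URL.format(symbol=s) for s in syms),
            "genecards_urls": ";".join(
                GENECARDS_URL.format(symbol=s) for s in syms),
        })
    return GeneReport(pd.DataFrame(rows))
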