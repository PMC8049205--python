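"""A/B compartment calls from Hi-C and switch detection between samples.

Compartments are read off the sign of PC1 of the correlation matrix of the
observed/expected-transformed map. The sign of PC1 is arbitrary, so it is
oriented against a covariate that tracks activity (binned expression, or gene
density): after orientation, positive PC1 = A (active), negative = B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import feature_analyzer
from .errors import AlignmentError, ValidationError
from .genome_model import BinIndex, ExpressionTrack, HiCMatrix

__all__ = ["CompartmentTrack", "SwitchSet", "call_compartments",
           "find_switches", "write_compartments_bed", "write_switches_bed"]


@dataclass
class CompartmentTrack:
    bins: BinIndex
    pc1: np.ndarray
    labels: np.ndarray               # 'A', 'B' or 'masked' per bin
    orientation_r: float = 0.0       # corr of pc1 with orientation covariate
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return self.labels != "masked"


@dataclass
class SwitchSet:
    """Maximal non-overlapping runs of bins whose A/B label differs."""

    regions: pd.DataFrame            # start_bin, end_bin (excl), direction
    bins: BinIndex

    def __len__(self) -> int:
        return len(self.regions)


def call_compartments(H: HiCMatrix,
                      orientation: ExpressionTrack | np.ndarray
                      ) -> CompartmentTrack:
    """Label bins A/B from the sign of oriented PC1.

    ``orientation`` is a per-bin activity covariate (an expression track or a
    gene-density vector); PC1 is negated when its Pearson correlation with the
    covariate over unmasked bins is negative. Bins with pc1 == 0, and masked
    bins, are labeled 'masked'.
    """
    cov = orientation.values if isinstance(orientation, ExpressionTrack) \
        else np.asarray(orientation, dtype=float)
    if cov.size != H.n_bins:
        raise AlignmentError("orientation covariate length must equal n_bins")
    pc1 = feature_analyzer.first_principal_component(H)
    m = H.mask.copy()
    labels = np.full(H.n_bins, "masked", dtype=object)
    if not np.any(pc1[m] != 0):
        warnings.warn("zero-variance correlation matrix: all bins masked",
                      stacklevel=2)
        return CompartmentTrack(H.bins, pc1, labels,
                                meta={"degenerate": True})
    r = 0.0
    c = cov[m]
    if np.std(c) > 0 and np.std(pc1[m]) > 0:
        r = float(np.corrcoef(pc1[m], c)[0, 1])
    if r < 0:
        pc1 = -pc1
        r = -r
    labels[m & (pc1 > 0)] = "A"
    labels[m & (pc1 < 0)] = "B"
    return CompartmentTrack(H.bins, pc1, labels, orientation_r=r)


def find_switches(a: CompartmentTrack, b: CompartmentTrack,
                  min_len: int = 1) -> SwitchSet:
    """Maximal runs of bins that change compartment between two tracks.

    A bin counts as switched when both tracks assign it an (unmasked) A/B
    label and the labels differ; runs shorter than ``min_len`` are dropped.
    Direction is recorded as 'A2B' or 'B2A' per run (runs never mix
    directions, since the start label flips between adjacent switched bins
    of different direction).
    """
    if a.bins != b.bins:
        raise AlignmentError("compartment tracks are on different bins")
    if min_len < 1:
        raise ValidationError("min_len must be >= 1")
    la, lb = a.labels, b.labels
    switched = (la != "masked") & (lb != "masked") & (la != lb)
    rows = []
    n = la.size
    i = 0
    while i < n:
        if switched[i]:
            j = i
            while j + 1 < n and switched[j + 1] and la[j + 1] == la[i]:
                j += 1
            if j - i + 1 >= min_len:
                rows.append({"start_bin": i, "end_bin": j + 1,
                             "direction": f"{la[i]}2{lb[i]}"})
            i = j + 1
        else:
            i += 1
    df = pd.DataFrame(rows, columns=["start_bin", "end_bin", "direction"])
    return SwitchSet(df, a.bins)


def write_compartments_bed(track: CompartmentTrack, path) -> None:
    """BED of maximal same-label bin runs, score = mean |pc1| of the run."""
    b = track.bins
    rows = []
    i = 0
    n = b.n_bins
    while i < n:
        lab = track.labels[i]
        j = i
        while j + 1 < n and track.labels[j + 1] == lab:
            j += 1
        if lab != "masked":
            rows.append((b.chromosome, int(b.starts[i]),
                         int(b.starts[j]) + b.resolution, lab,
                         float(np.abs(track.pc1[i:j + 1]).mean())))
        i = j + 1
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_switches_bed(switches: SwitchSet, path) -> None:
    b = switches.bins
    rows = [(b.chromosome, int(b.starts[r.start_bin]),
             int(b.starts[r.end_bin - 1]) + b.resolution, r.direction)
            for r in switches.regions.itertuples(index=False)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
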