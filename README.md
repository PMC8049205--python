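# fourdn

Network-based analysis of time-series genome structure (Hi-C) and function
(RNA-seq) — the "4D Nucleome" view of a cell: how 3D genome organization and
gene expression change together through processes like the cell cycle,
differentiation or reprogramming.

`fourdn` is for computational biologists who already have processed data:
binned intra-chromosomal Hi-C contact matrices and gene-level expression
tables, one pair per time point, described by a small metadata CSV. It
provides:

- **Structure-function feature analysis.** For each time point *m* with
  contact matrix A⁽ᵐ⁾ ∈ ℝⁿˣⁿ and binned log₂ expression r⁽ᵐ⁾ ∈ ℝⁿ, the
  contact map is treated as a weighted network and four centralities are
  computed per bin — degree b_deg, eigenvector b_eig, betweenness b_bet,
  closeness b_close — giving the feature matrix
  X⁽ᵐ⁾ = [b_deg, b_eig, b_bet, b_close, r] ∈ ℝⁿˣ⁵. Columns are z-scored
  jointly over all time points, all time points are embedded into one common
  low-dimensional space (PCA, Laplacian Eigenmaps, t-SNE or UMAP), loci are
  ranked by the path length of their feature trajectory, and the genes in the
  top loci are reported with NCBI / GeneCards links. Structure-vs-function
  *phase planes* trace individual loci over time.
- **A/B compartments and switches.** PC1 of the correlation of the
  observed/expected map, sign-oriented against expression so that A = active;
  maximal runs of bins that flip compartment between samples are reported.
- **Network and tensor entropy.** Von Neumann entropy −Σⱼ λⱼ ln λⱼ of the
  unit-trace graph Laplacian quantifies how (dis)organized chromatin
  structure is; the tensor generalization scores k-uniform hypergraphs built
  from multi-correlations √(1 − det R) of locus subsets, with λⱼ the
  normalized singular values of the Laplacian tensor's mode-1 unfolding.
- **Larntz–Perlman (LP) test.** A statistical test of equality of k ≥ 2
  Hi-C-derived correlation matrices: Fisher transforms Z_ij = arctanh C_ij,
  per-coefficient statistics S_ij = (n_obs − 3) Σₘ (Z_ij⁽ᵐ⁾ − Z̄_ij)², test
  statistic T = max_{i<j} S_ij referred to χ²_{k−1} at the Šidák level
  ε(α) = (1 − α)^{2/(n(n−1))}, with a conservative p-value
  1 − F(T)^{n(n−1)/2}.
- **A synthetic-data module** that simulates block-compartment Hi-C with
  power-law distance decay and Poisson counts, compartment-correlated
  expression, and time series with planted structure-function changes — used
  throughout the test suite and usable as a sandbox.

## Worked example

Simulate a three-time-point experiment on a 300-bin chromosome with ten loci
that progressively flip compartment and gain expression, then rank loci by
structure-function change:

```python
import numpy as np
from fourdn import synthetic, hic_norm, feature_analyzer as fa

loci = (12, 45, 80, 113, 150, 181, 210, 244, 270, 291)
cfg = synthetic.SimConfig(n_bins=300, seed=1, changed_loci=loci)
_, hics, exprs, genes = synthetic.simulate_timeseries(cfg, T=3)

hics = [hic_norm.balance(H) for H in hics]
mask = fa.shared_mask(hics)
stack = [fa.build_feature_matrix(H, r, mask=mask)
         for H, r in zip(hics, exprs)]
ranking = fa.rank_changes(fa.normalize_features(stack), top_k=10)
print(sorted(ranking.top_bin_ids.tolist()))
print(np.round(ranking.scores[ranking.order[:3]], 2))
```

prints

```
[12, 45, 52, 80, 113, 150, 210, 244, 270, 291]
[13.44 12.22 11.22]
```

— nine of the ten planted loci lead the ranking (locus 181 is narrowly
displaced by a noisy neighbour at this seed), and the largest trajectory
path lengths (≈ 11–13 in z-score units across the five features) stand far
above the noise floor of unchanged loci. The same pipeline is available
from the shell:

```sh
fourdn simulate --n-bins 300 --changed-loci 12,45,80 --seed 1 --out fixture/
fourdn features fixture/samples.csv --chromosome chrS --resolution 100000 \
    --out results/ --method pca
fourdn lp fixture/samples.csv --chromosome chrS --resolution 100000 \
    --region 0-60 --out results/
```

`features` writes `embedding.tsv`, `ranking.tsv`, `report.tsv`/`.html`
(genes with database links) and a phase-plane figure; `lp` writes a JSON
with T, the Šidák-corrected critical value, the conservative p-value, and
the rejection decision.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full stack from scratch on a seeded synthetic experiment —
simulation, balancing, feature assembly, change ranking, compartment and
switch calls, network entropy per time point, and an LP comparison of the
first and last time points — printing a summary to stderr and writing its
result JSON to `--out`.
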