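# Methods

This note documents the models and procedures implemented in `fourdn`, the
choices made where the underlying methodology is ambiguous, and what the
synthetic test bed does and does not establish.

## Data model and conditioning

All analyses operate per chromosome on a uniform `BinIndex` (0-based
half-open coordinates, BED convention on output). A `HiCMatrix` must be
symmetric (relative asymmetry ≤ 1e-6 is averaged away; anything larger is a
format error, never silently repaired) and non-negative; bins whose row sum
is zero are masked, and every multi-time-point analysis restricts itself to
the *intersection* of the masks so feature rows stay aligned across time.

Gene expression is aggregated to bins by gene **midpoint** (a gene spanning
a bin boundary is not split; the midpoint rule is unambiguous), with
log2(TPM + pseudocount) applied **per gene before averaging**. The per-gene
log bounds the influence of a single very high-TPM gene on its bin;
`mean_then_log=True` gives the alternative reading. Default pseudocount 1.

Contact-map conditioning is: balancing → observed/expected →
log2(x+1) → row-wise Pearson correlation. Balancing is the square-root
variant of iterative proportional fitting (divide by the outer square root
of the row-sum vector), stopping when every unmasked row sum is within
`tol` (default 1e-6) of their mean; non-convergence returns the last
iterate flagged `balance_converged=False`. Observed/expected divides each
entry by the mean of its |i−j| stratum computed over unmasked pairs.
Published Hi-C workflows differ on which of these steps precede
correlation, so each step is switchable; the default pipeline is this
package's choice, not a claim about any upstream toolbox.

## Centralities (structure features)

The contact map is a weighted graph on bins with the diagonal
(self-contact, an assay artifact) removed.

- *Degree*: off-diagonal row sums (node strength).
- *Eigenvector*: Perron vector of the unmasked adjacency, power iteration
  to 1e-10, unit 2-norm. On a disconnected graph it is computed on the
  largest component (others 0) with a warning.
- *Betweenness* and *closeness* need an edge length; contact frequency is a
  similarity, so length = 1/weight (stronger contact = closer), with
  −log(w/max w) available as `distance="neglog"`. Betweenness is normalized
  by (n−1)(n−2)/2; closeness is (n−1)/Σⱼ d(i,j), falling back to the
  harmonic form Σⱼ d(i,j)⁻¹/(n−1) (flagged in metadata) when any pair is
  unreachable.

Betweenness delegates to igraph's C implementation; the test suite checks
all four measures against brute-force oracles (dense eigendecomposition,
Floyd–Warshall path counting, per-source Dijkstra) on random graphs.

## Feature analysis and change ranking

X⁽ᵐ⁾ = [b_deg, b_eig, b_bet, b_close, r] per time point. Columns are
z-scored **jointly** over the row-concatenation of all time points:
per-time-point normalization would erase exactly the between-time-point
shifts the ranking is meant to find. Zero-variance columns map to 0.

The change score of a locus is the Euclidean path length of its normalized
5-feature row across the ordered time points (sum of consecutive
between-time-point distances). This is deterministic and reproducible,
unlike distances measured in a stochastic embedding (t-SNE/UMAP), which is
why scoring happens in feature space; the ranking and the embedding are
decoupled. Identical trajectories score exactly 0 and ties rank by bin
index (stable sort).

The "common low-dimensional space" across time points is implemented as
concatenate-then-embed: all n·T rows are embedded together and split back,
the minimal construction under which per-time-point coordinates are
mutually comparable. PCA (column-centered SVD, deterministic sign: each
component's largest-magnitude loading is positive) and Laplacian Eigenmaps
(symmetric k-NN graph with distance ties included — so duplicated points
get identical neighborhoods — binary weights by default, random-walk
Laplacian eigenvectors 2..d+1) are implemented in-repo and are bitwise
deterministic. t-SNE and UMAP delegate to scikit-learn and umap-learn with
an explicit seed and are labeled stochastic. Defaults: LE k_neighbors=15,
t-SNE perplexity 30 (reduced automatically for tiny inputs), UMAP
n_neighbors=15 / min_dist=0.1, seed 42.

Gene reports join top loci to genes by interval overlap and emit fixed-template
NCBI / GeneCards URLs; no network access is ever performed.

## Compartments

PC1 of the correlation matrix of the observed/expected map. Its sign is
arbitrary, so it is oriented against an activity covariate — binned
expression by default, gene density as a fallback — by flipping when the
Pearson correlation is negative; after orientation, pc1 > 0 is A (active)
and pc1 < 0 is B. Bins with pc1 exactly 0 are left unassigned ("masked")
rather than tie-broken. No smoothing is applied to pc1 before labeling.
Switch regions between two tracks are maximal runs of bins where both
labels are assigned and differ *in the same direction* (a run is never
allowed to mix A→B and B→A bins), filtered by a minimum run length
(default 1 bin).

## Network entropy

For a weighted graph with adjacency A (|off-diagonal correlation| for
correlation input, the balanced contact matrix for contact input), the
Laplacian L = D − A scaled by 1/trace(L) is positive semi-definite with
unit trace, so its eigenvalues λⱼ form a probability distribution and the
von Neumann entropy −Σⱼ λⱼ ln λⱼ (natural log, nats) is well defined. This
Laplacian-density convention is the central interpretive decision of the
entropy module: a raw contact or correlation matrix can have negative
eigenvalues, which cannot enter the entropy formula as probabilities. The
alternative convention — normalized |eigenvalues| of the adjacency itself —
is available via `convention="eigenvalues"` but is not the default.
Useful laws (all regression-tested): complete graph K_n has entropy
ln(n−1); a single edge has entropy 0; 0 ≤ H ≤ ln(rank).

## Tensor entropy

Simultaneous interaction of k ≥ 3 loci is modeled by a k-uniform hypergraph
whose edge weight for a locus subset is the multi-correlation
ρ = √(1 − det R), with R the principal correlation submatrix — ρ reduces to
|r| at k=2 and lies in [0,1] for PSD R, which is what makes the tensor
entropy a strict extension of the network entropy (verified numerically at
k=2 to 1e-10). Edges below a threshold are dropped. The Laplacian tensor
places node degrees (sum of incident edge weights) on the super-diagonal;
the "generalized singular values" are the singular values of its mode-1
unfolding (n × n^{k−1}) — for a supersymmetric tensor all mode unfoldings
share singular values, making mode 1 canonical — normalized to sum 1.
Storage is O(n^k), so hypergraph construction caps unmasked n at 64 by
default; the CLI coarsens bins by aggregation first.

## Larntz–Perlman test

Implemented exactly as stated in the module docstring. Two readings were
fixed here: (1) the "(n−3)" variance factor of Fisher's z refers to the
number of **observations** behind each correlation coefficient, exposed as
the explicit parameter `n_obs` (when correlations come from contact-profile
rows over a region, n_obs = number of jointly unmasked bins in the region);
(2) perfect correlations (|C| = 1, common in small toy matrices) are
clipped at 1 − 1e-12 before arctanh rather than erroring, with the clip
count reported. The p-value 1 − F(T)^{n(n−1)/2} inverts the critical-value
relation exactly and is conservative under positive dependence of the
coefficients; no correlation-adjusted refinement is attempted.

Calibration caveat: with weakly dependent coefficients and small n_obs
(~30), the χ²_{k−1} approximation to (n_obs−3)Σ(Z−Z̄)² leaves the max-type
test near-nominal rather than conservative (empirical type-I error a
couple of points above α). Under the strong positive dependence that
Hi-C-derived correlation matrices actually exhibit — the compartment-block
population correlation used in the null-calibration tests — the Šidák
bound dominates and the test is conservative, which is the regime the
procedure is intended for.

## Synthetic world

The generator simulates one chromosome arm: n = 200 bins of 100 kb by
default, alternating A/B blocks of 25 bins (~2.5 Mb compartments),
expected contacts E_ij ∝ (1+|i−j|)^(−α) · (1 + γ·[same compartment])
scaled to a total depth of 5·10⁵ expected intra-chromosomal read pairs,
Poisson-sampled and mirrored. Defaults: α = 1 (the canonical contact-decay
exponent), γ = 2 (strong compartmentalization). Expression is
effect·[A] + N(0, sd) in log2 space (effect 2, sd 0.5 — an ~4-fold A/B
expression difference with moderate biological noise), exponentiated to a
TPM-like scale and re-logged through the standard pipeline. Time series
interpolate planted loci linearly from their original compartment to the
flipped one and add a progressive expression shift (default 4 log2 units
at the final time point, ≈ 3.5 column standard deviations after joint
z-scoring). Poisson counts (not negative binomial): no overdispersion is
modeled; a parameter slot is reserved.

What a green test establishes: the pipeline recovers planted block
compartments, planted structure-function changes, and planted correlation
differences under Poisson noise at realistic depth, and every statistic
matches its independent oracle. What it does not establish: behavior under
real-data pathologies — copy-number variation, translocations,
restriction-fragment bias, overdispersed counts, unmappable regions — none
of which the generator emulates.

## Numerical conventions

- Balancing tolerance 1e-6 (relative, vs the mean row sum), max 200 sweeps.
- Power iteration tolerance 1e-10; PCA/LE sign fixed by the
  largest-magnitude-loading rule, first index winning ties.
- Entropy spectra are clipped at 0 (floor −1e-12) and must sum to 1 within
  1e-10; 0·ln 0 := 0.
- LP argmax ties break to the lexicographically smallest (i, j).
- All simulators draw from `numpy.random.default_rng` seeded through
  `SeedSequence([seed, stream, timepoint])`: bitwise reproducible, streams
  independent across time points.

## Known limitations

- Only intra-chromosomal maps; no .hic (juicer) parsing; `.cool` reading is
  a minimal HDF5-schema reader (bins/pixels for one chromosome), ignoring
  stored balancing weights.
- Compartment calling has no sub-compartment or TAD support and applies no
  PC1 smoothing.
- The LP test's p-value is conservative by construction; its near-nominal
  behavior under weak dependence at small n_obs is inherent to the
  Fisher-z χ² approximation (see above).
- Hypergraph entropy is exponential in k; k ≤ 4 and n ≤ 64 enforced.
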