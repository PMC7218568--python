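# Methods

## Model and procedure

The object of study is a sparse non-negative integer matrix **B** of fragment
counts, rows = cells, columns = called peaks.  The working hypothesis is that
chromatin accessibility is organized in *modules*: groups of peaks whose
accessibility rises and falls together across cells, whether because they sit
in the same regulatory domain, share upstream regulators, or are spatially
adjacent.  An **accesson** is such a module, discovered directly from the
count matrix:

1. B′ᵢⱼ = log₂(Bᵢⱼ · 10⁴ / Σⱼ′ Bᵢⱼ′ + 1).  The per-cell rescaling removes
   library-size differences; the log tames the heavy count tail; the +1 keeps
   zeros at zero, so B′ preserves the sparsity pattern of B.  Cells with zero
   total count map to zero rows rather than dividing by zero.
2. Each peak is a vector over cells.  Peaks are projected onto the top 40
   principal components of B′ (columns centered; exact SVD; component signs
   fixed so the largest-magnitude coordinate of each component is positive,
   making the embedding reproducible).  A K = 10 nearest-neighbor graph
   (Euclidean, self excluded, symmetrized by union) supplies the connectivity
   constraint, and Ward agglomeration restricted to graph edges cuts the
   peaks into a requested number of accessons (default 600).
3. The accesson matrix **M** sums *raw* counts per accesson and cell — raw
   rather than normalized counts, so the column sums of **M** conserve each
   cell's total exactly and downstream users can renormalize as they wish.
   **M**ₐ is **M** with each cell row z-scored (population SD; constant rows
   map to zero) or divided by its sum ("probability").
4. Cells are clustered on **M**ₐ: K-neighbor graph (default 20 neighbors),
   then Louvain modularity optimization (resolution 1.0, explicit seed,
   communities relabeled by decreasing size), which chooses the number of
   clusters itself.  When a cluster count is imposed, the same
   graph-constrained Ward procedure used for peaks is applied to cells.
5. Agreement between partitions is the Adjusted Rand Index computed from the
   contingency table nᵢⱼ with row/column sums aᵢ, bⱼ and total n:

   ARI = [Σᵢⱼ C(nᵢⱼ,2) − Σᵢ C(aᵢ,2)·Σⱼ C(bⱼ,2)/C(n,2)] /
         [(Σᵢ C(aᵢ,2)+Σⱼ C(bⱼ,2))/2 − Σᵢ C(aᵢ,2)·Σⱼ C(bⱼ,2)/C(n,2)]

   evaluated in exact rational arithmetic (binomials as Python integers, one
   final float conversion), with reference cells labeled `"unknown"` removed
   first.

Downstream modules reuse the decomposition: TSS ±20 kb mean-count gene
scores with per-gene rescaling to a 10 000 total across cells; Welch
one-vs-rest *t*-tests with Benjamini–Hochberg correction and a
pseudocounted fold change ((mean₊ + 0.01)/(mean₋ + 0.01)); a sparse-data
path that tests accesson columns first and reports genes whose TSS window
intersects any peak of a significant accesson; one-sided Fisher's exact
association between two families of differential gene sets inside a common
universe, reported as −ln P and z-scored by row then column; per-cell
annotation scores as the product of a (terms × accessons) −log-significance
weight matrix with **M**ᵀ, row z-scored; sliding-window super-enhancer
calls; and accesson-space PCA (top 5 PCs) as trajectory features, with
per-PC correlation against library size reported because the first
component of raw accesson counts typically tracks sequencing depth.

## Parameters that matter

| parameter | default | role |
| --- | --- | --- |
| `n_pcs` (peak embedding) | 40 | dimensionality of the peak space; a few PCs miss fine structure, hundreds re-admit noise |
| `k` (peak KNN) | 10 | sparsity of the Ward constraint graph |
| `n_accessons` | 600 | partition size; clustering is stable over ~500–1500, requests above the peak count are capped |
| accesson normalization | z-score | per-cell scale removal; probability variant divides by the row sum instead |
| `n_neighbors` (cells) | 20 | cell-graph density for Louvain |
| `resolution` | 1.0 | Louvain modularity resolution |
| gene-score `window` | 20 000 bp | TSS window for gene activity (interval overlap, half-open) |
| differential `p_cutoff`, `fc_cutoff` | 0.05, 2.0 | BH-adjusted significance and fold-change floors |
| SE `window`, `step`, `min_peaks`, `p_cutoff` | 1 Mb, 100 kb, 10, 0.01 | super-enhancer scan geometry and thresholds |
| QC `pf_cutoff`, `nf_cutoff` | data-dependent | strict `>` cuts on fraction-in-peaks and total fragments |

## Super-enhancer null

Only the window width (1 Mb) and the significance level (P < 0.01) are fixed
by the method's definition; the rest of the scan is this package's own
operationalization and every knob is exposed.  Windows slide by 100 kb; a
peak belongs to a window through its midpoint.  The statistic for a
(window, accesson) pair is the member fraction — that accesson's peaks over
all peaks in the window.  The null pool collects these fractions for *every*
accesson present in every window holding at least `min_peaks` peaks in
total; sparser windows are excluded because a lone peak would contribute a
degenerate fraction of 1.  Candidates additionally need `min_peaks` member
peaks, and their empirical P is the +1-smoothed upper-tail rank of their
fraction in the pool.  Overlapping windows of the same accesson merge into
one reported interval carrying the best statistics.

## Synthetic data: what it emulates and what it does not

`generate_dataset` draws counts as

  Bᵢⱼ ~ Poisson(depthᵢ · rate[b(j), t(i)] · εᵢ,b(j))

where b(j) is peak j's planted block, t(i) cell i's planted type,
depthᵢ = 2.0·LogNormal(0, 0.4) the library-size factor, rate the on/off
design (0.5 / 0.02 per peak) over blocks × types, and ε a lognormal factor
(σ = 0.8, unit mean) *shared by all peaks of a block within a cell*.  The
shared factor is the defining feature: it plants co-fluctuation, the signal
that accesson discovery exploits, and it is what makes 30 blocks
identifiable even though only 2³−1 distinct on/off patterns exist over 3
types.  The amplitude was fixed together with the depth scale when the
generator was designed: weaker co-fluctuation makes blocks statistically
indistinguishable from one another, while much stronger co-fluctuation
creates cells whose profiles sit between type centroids and whose Louvain
assignment becomes unstable; a median of ~600 in-peak fragments per cell
restores block identifiability at moderate amplitude.  Type on/off patterns
are drawn uniformly subject to no block being off everywhere and every pair
of type profiles differing in at least a third of the blocks, so the planted
types are genuinely distinct.  Gradient mode replaces types by a latent
uniform pseudotime tᵢ with block rates linear in t (randomly increasing or
decreasing per block).

The corruption protocols are nested per seed: down-sampling attaches one
uniform per read and keeps it iff u < fraction (marginally Binomial
thinning), and zeroing takes the first round(f · nnz) elements of one seeded
permutation of the nonzeros (marginally a uniform subset).  Nesting makes
successive corruption levels supersets of each other — the standard paired
design for degradation curves, removing spurious non-monotonicity that
independent redraws would inject.

The generator does **not** emulate fragment-length structure, Tn5 sequence
bias, GC content, doublets, batch effects, or peak-calling artifacts.
Passing tests on these data therefore demonstrate that the implementation
recovers planted co-accessibility and cell structure under realistic
sparsity and depth variation — not that the method is robust to every
failure mode of real scATAC-seq.

## Numerical choices and degenerate inputs

- KNN ties at the k-th distance resolve by lower index; all graph
  construction is deterministic.
- Constrained Ward runs independently inside each connected component of
  the constraint graph (cluster quota apportioned by largest remainder on
  component size), so a merge never crosses a missing edge; if the graph has
  more components than requested clusters, the components are returned with
  a warning.
- Louvain uses igraph's multilevel algorithm with an explicitly seeded RNG;
  an edgeless graph yields singleton clusters with a warning.
- z-scores use the population (n) denominator throughout; constant rows
  z-score to zero rather than NaN.  Pearson correlations of constant rows
  are set to 0 with a warning.
- Fisher P values use the natural log in −log transforms; the z-score order
  (rows then columns) and the test sidedness are switchable flags because
  neither is forced by the definition.
- Empty filter results raise with the before/after counts instead of
  returning silent empty matrices.
- MTX orientation is resolved against the sidecar files; a square matrix
  requires an explicit orientation flag.

## Problem sizes

Tests and the acceptance script run on 150 cells × 1200 peaks (30 blocks ×
40 peaks, 3 types × 50 cells), the super-enhancer scan on 2020 peaks over a
100 Mb chromosome, chosen so planted effects are comfortably detectable and
a full suite completes in minutes on one CPU.  All pipeline stages are
vectorized and have been exercised unchanged on matrices an order of
magnitude larger.

## Known limitations

- "KNN clustering" with a user-fixed cluster count is realized as
  graph-constrained Ward; other readings (e.g. k-means on graph features)
  are defensible.
- The peak KNN graph is symmetrized by union; intersection would give a
  sparser constraint and slightly different accessons.
- The TSS-proximity QC metric is computed from in-peak counts only, an
  approximation to the read-level quantity available upstream of peak
  calling; it is reported as such, not claimed equivalent.
- Trajectory inference itself (minimum spanning trees, graph embeddings) is
  out of scope: the package emits the accesson-PC features such engines
  consume and summarizes scores along a pseudotime they return.
- No batch-effect correction and no doublet handling.
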