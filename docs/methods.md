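# Methods

This note records the mathematical definitions, the numerical design
choices, and the intent and limits of the synthetic benchmark, in the
package's own notation.  Everything here is implemented in
`src/cesfw/`; file pointers are given per section.

## 1. Minority-state activity normalisation (`activity.py`)

Raw counts are mapped per gene to activities in [0, 1]:

1. divide by the p-th percentile (default p = 97.5) of the gene's
   **strictly positive** entries, then clip to 1.  Restricting the
   percentile to positive entries keeps the divisor meaningful for
   sparsely expressed genes, where the percentile over all cells would
   be 0.
2. if the resulting activity mass exceeds n/2, replace `a` by `1 − a`
   so the minority state carries the signal (an exact tie is left
   unflipped).  Entropy sorting is symmetric under joint
   complementation, so this only fixes an orientation convention.

Two numerical choices make the normalisation exactly invariant, at the
bit level, to positive per-gene rescaling and to cell reordering:

- the percentile uses the **order statistic** (`method="lower"`), not
  linear interpolation.  An order statistic of `λ·v` is exactly
  `λ · (order statistic of v)` in floating point, so `(λv)/(λs)` and
  `v/s` are the same floats; interpolated percentiles are not
  scale-exact.
- cells are put into a canonical order (sorted by cell id) before any
  accumulation, so floating-point sums do not depend on input order.

Genes expressed in fewer than `min_cells_expressing` cells are dropped
with a log message.

## 2. Entropy sorting (`es_core.py`)

For a pair of activity vectors the **reference feature** (RF) is the
one with the smaller cardinality `m_rf = Σ a` (ties broken toward the
lower gene index), the other is the **query feature** (QF) with
cardinality `m_qf`; the overlap is `x = Σ a·b` (pointwise product; a
pointwise-minimum operator is available as a config switch).  With `h`
the binary entropy in bits, the conditional entropy of the QF given
the RF as a function of the overlap is

```
H(x) = (m_rf/n)·h(x/m_rf) + ((n−m_rf)/n)·h((m_qf−x)/(n−m_rf))
```

`H` is concave in `x` and maximised at the independence overlap
`x_me = m_rf·m_qf/n`, where it equals the QF's marginal entropy
`h(m_qf/n)` — this identity is asserted to 1e-12 in the tests.

**Entropy Sort Score.** Let `G(x) = H(x_me) − H(x)` be the entropy
gap.  The ESS is `±G(x)/G(x_bound)`, positive when `x > x_me` (bound =
upper overlap bound) and negative when `x < x_me` (bound = lower
bound), so ESS ∈ [−1, 1] with 0 at independence and ±1 at the bounds.

**Attainable (rearrangement) bounds.** On binary vectors the overlap
bounds are the classical `x_max = m_rf` and
`x_min = max(0, m_rf + m_qf − n)`.  On continuous activities those
discrete bounds are not attainable: even two *identical* vectors give
`x = Σ a² < m`.  Normalising the gap at unattainable bounds deflates
positive scores relative to negative ones and breaks the anchor "ESS =
1 for identical features".  The package therefore normalises at the
**rearrangement bounds** of the overlap,

```
x_hi = Σ sort(a)·sort(b)        (maximal coupling)
x_lo = Σ sort(a)·reverse(sort(b))  (minimal coupling)
```

which are the largest and smallest overlaps attainable by any
reordering of one vector against the other (the classical
rearrangement inequality).  On 0/1 vectors these reduce *exactly* to
`m_rf` and `max(0, m_rf + m_qf − n)`, so every discrete contract is
preserved; on continuous data identical vectors again score exactly 1.
The continuous path restricted to binary input is bit-identical to the
discrete path — an invariant asserted in the acceptance tests.

**Error Potential.** Under random permutation of one binary feature
the overlap is hypergeometric with standard deviation

```
σ₀ = sqrt( m_rf·m_qf·(n−m_rf)·(n−m_qf) / (n²·(n−1)) )
```

`EP = |x − x_me| − z·σ₀` (default z = 1) is positive when the observed
deviation from independence exceeds `z` null standard deviations; the
tests check its sign against an explicit permutation oracle.  The
gated, thresholded matrix `dEPs = max(EP, 0)` (zero diagonal) is the
edge-weight matrix of the co-occurrence network.

**Error scenarios.** `classify_error_scenario` labels which 2×2
contingency cell is the minimal inconsistency to repair when sorting
toward the nearer bound; the rule table (ids 1–5, 0 = at
independence) is documented in the module and enumerated exhaustively
in the tests.

**Blocked computation.** `pairwise_matrices` computes `x`, `x_hi`,
`x_lo` for all pairs as three matrix products (the `x_hi/x_lo`
products on column-sorted copies of the matrix), chunked to bound
memory; binary dot products are exact in floating point, so the
blocked path equals the scalar per-pair path bit-for-bit.  A memory
cap produces an actionable error suggesting pre-filtering.

## 3. Feature weighting (`weighting.py`)

Gene `j`'s **centrality** is the dEPs-weighted mean of its signed ESS
over all partners:

```
c_j = Σ_{i≠j} dEPs_ij·ESS_ij / Σ_{i≠j} dEPs_ij     (0 if no edges)
```

Its **weight** divides centrality by a slowly growing function of the
edge count `e_j = #{i : dEPs_ij > 0}`:

```
w_j = c_j / log2(e_j + 2)
```

The logarithmic penalty (config: `log2`; `linear` and `none` are also
available) encodes the observation that informative genes sit in small
coherent networks, whereas generic highly expressed genes accumulate
many weak edges.  Ranks break weight ties by gene id so the output is
deterministic.

## 4. Dataset-enrichment exclusion (`batch.py`)

For each dataset label, a binary membership indicator is scored
against every gene (scalar ESS/EP).  A gene is excluded when some
dataset gives `EP > 0` **and** `ESS ≥ 0.5` — i.e. its activity is both
significantly and strongly nested inside one dataset.  The report
keeps the best-scoring dataset as evidence per excluded gene and warns
that genuinely dataset-exclusive cell types would be removed too; with
a single dataset the step warns and is a no-op.  Only positive
enrichment is gated: a gene *absent* from one of many datasets is not
excluded.

## 5. Selection, gene clusters, embedding (`selection.py`)

Top-k genes by weight (default k = 4000, capped at the gene count) are
selected.  The selected ESS submatrix is hierarchically clustered
(correlation distance, average linkage); a cluster whose mean
centrality exceeds 1.5× the median of cluster means is flagged as a
high-centrality hub (generic transcription/translation signal in real
data) — flagged, never silently dropped.  Cell embedding and
clustering are thin wrappers over umap-learn
(n_neighbors = 50, min_dist = 0.1, correlation metric, seeded) and
scikit-learn agglomerative clustering (correlation, average linkage,
default 30 clusters) with per-cluster mean silhouettes.

## 6. Downstream ESS statistics (`markers.py`)

- **Marker ranking**: signed ESS of each gene against a
  minority-oriented cell-subset indicator; because ESS declines when
  activity leaks outside the subset, specific markers outrank equally
  frequent but leaky genes.
- **Staged lineage ranking**: the same ranking per stage of a strictly
  nested sequence of cell-state sets.
- **Embryo co-occurrence**: per-embryo state composition vectors,
  normalised like genes (max scaling + minority orientation), scored
  pairwise by ESS — positive for states that appear in the same
  embryos, negative for mutually exclusive ones.
- **Pseudobulk correlation**: 1 − Pearson r between per-state mean
  expression vectors over the selected genes (NaN for constant
  states).
- **kNN label transfer**: majority vote of k = 20 Euclidean neighbours
  in embedding space, ties toward the smaller label, with optional
  per-condition composition tables.

## 7. Synthetic benchmark (`benchmark.py`)

The benchmark emulates a branching differentiation experiment with
known ground truth.  Cell states sit on a tree (a 5-state chain or a
7-state bifurcating tree); each non-root state owns a module of "TF"
genes active in that state and its descendants (the root/progenitor
state is marked by the *absence* of branch modules — a gene active in
the root and all descendants would be expressed everywhere and carry
no state information).  "HK" genes are active in all cells.  Counts
are negative binomial (dispersion 1) times independent Bernoulli
retention (dropout 0.2).  Within a module, each cell carries a shared
Gamma(shape 1, mean 1) activity factor multiplying the module mean, so
module genes co-fluctuate along the trajectory as they do in regulated
networks; without it module genes would be conditionally independent
given the state and the co-expression signal the method detects would
be an artifact of the state boundaries only.

Four presets cross the two topologies with two expression regimes,
fixed by the average non-zero expression of TF and HK genes: a low-HK
regime (TF 9.75, HK 1.26) and a high-HK regime (TF 1.74, HK 115).
The state means are calibrated analytically: for HK genes,
`E[X|X>0] = μ/(1−P₀(μ))` is inverted by root finding; for TF genes the
pooled non-zero mean over active and background cells is inverted with
the Gamma factor integrated into the zero probability.  Bernoulli
dropout thins which entries survive without changing surviving
non-zero values, so it cancels from the calibration.  Realised anchors
land within a few percent of the targets (asserted within 10% in unit
tests, 20% in the acceptance suite).

Sizes (~1,000 cells, ~100 TF + 400 HK genes, 3 seeds) are chosen so
the whole grid runs in well under a minute on one CPU while leaving
enough cells per state for stable entropy estimates.

Baselines are deliberately plain stand-ins for highly-variable-gene
selection: variance of `log2(1+x)`, and the residual of log variance
after a quadratic fit on log mean.  ROC/PR curves collapse score ties
into single threshold steps; the trapezoidal AUROC then equals the
tie-averaged rank statistic (cross-checked against scikit-learn in the
tests, which is used as oracle only).

What the generator does **not** emulate: library-size variation,
gene–gene regulatory lag, doublets, or ambient contamination.  Its
purpose is a controlled TF-vs-HK discrimination task, not a full
scRNA-seq simulator.

## 8. Determinism

The pipeline stages are deterministic by construction (canonical cell
order, exact binary dot products, tie rules by gene id); the only
stochastic component is UMAP, which is seeded from the single
`RunConfig.seed`.  Fixed inputs therefore reproduce every artifact
byte-for-byte, and cell permutation or positive per-gene rescaling of
the input leaves the feature-weight table bit-identical — both
asserted in the acceptance tests.

## 9. Limitations

- ESS is a pairwise statistic; higher-order redundancy between
  modules is only captured indirectly through the edge-count penalty.
- The EP gate uses a one-standard-deviation threshold, not a
  calibrated p-value; with very many cells almost any pair becomes
  "significant" and the signal moves entirely into the ESS magnitude.
- Dataset-enrichment exclusion removes genuinely dataset-exclusive
  cell-type markers along with technical artifacts; the report exists
  so users can audit and override.
- Continuous-overlap entropy sorting treats activities as soft
  memberships; heavy-tailed activity distributions compress after the
  percentile clip, which is intended but discards within-tail
  gradation.
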