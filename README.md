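# cesfw — continuous Entropy Sort Feature Weighting

`cesfw` selects informative genes from single-cell RNA-seq count
matrices without clustering the cells first.  Instead of ranking genes
by expression variance — which systematically favours highly expressed
genes — it scores every *pair* of genes by how improbably often they
are active in the same cells, then ranks each gene by how strongly it
participates in networks of such significantly co-occurring genes.
Genes that mark cell states co-occur with the other genes of their
state's programme; housekeeping genes, however highly expressed, do
not.

## The method in brief

1. **Activity normalisation.** Each gene's counts are divided by a
   high percentile (default 97.5) of its strictly positive values and
   clipped to 1, giving per-cell activities in [0, 1].  Genes active in
   a majority of cells are complemented so that the *minority* state
   carries the signal.
2. **Entropy sorting.** For a pair of genes with cardinalities
   `m_rf ≤ m_qf` (sums of activity over `n` cells) and overlap
   `x = Σ a·b`, the conditional entropy `H(x)` of the query feature
   given the reference feature is a concave function of `x`, maximised
   at the independence point `x_me = m_rf·m_qf/n`.  The **Entropy Sort
   Score** (ESS) is the entropy gap `H(x_me) − H(x)` normalised by its
   value at the attainable overlap bound on the relevant side, signed
   by the direction of deviation: +1 means perfectly nested activity,
   0 independence, −1 perfect avoidance.  On binary data the attainable
   bounds reduce exactly to the classical discrete bounds
   (`m_rf` and `max(0, m_rf+m_qf−n)`).
3. **Significance gate.** The **Error Potential**
   `EP = |x − x_me| − z·σ₀` compares the observed deviation with the
   standard deviation `σ₀` of the overlap under random permutation of
   one feature.  Only pairs with `EP > 0` count as edges.
4. **Feature weighting.** Each gene's centrality is the EP-weighted
   mean ESS over its significant partners; its weight divides that
   centrality by `log2(edge_count + 2)` so that genes with a few strong
   partners outrank promiscuous hubs.  The top-k genes by weight are
   selected.

Downstream utilities cover dataset-enrichment ("batch") gene exclusion,
hierarchical gene-cluster partitioning with hub flagging, UMAP
embedding and agglomerative sample clustering, ESS-based marker
ranking, per-embryo cell-state co-occurrence, pseudobulk correlation
distances, and kNN label transfer.  A synthetic benchmark with known
TF/housekeeping ground truth exercises the whole workflow.

## Worked example: one gene pair

Two binary genes over 100 cells: the reference gene is active in 20
cells, the query in 30, and they overlap in 12 — twice the 6 cells
expected under independence.

```python
import numpy as np
from cesfw import make_pair, conditional_entropy, ess, error_potential

a = np.zeros(100); a[:20] = 1                 # reference gene
b = np.zeros(100); b[:12] = 1; b[20:38] = 1   # query gene, overlap 12
pair = make_pair(a, b)
print("independence overlap x_me =", pair.x_me)
print("H at observed overlap     =", round(conditional_entropy(pair, pair.x), 6))
print("H at independence         =", round(conditional_entropy(pair, pair.x_me), 6))
print("entropy sort score (ESS)  =", round(ess(pair), 6))
print("error potential (EP)      =", round(error_potential(pair), 6))
```

Output:

```
independence overlap x_me = 6.0
H at observed overlap     = 0.809544
H at independence         = 0.881291
entropy sort score (ESS)  = 0.160708
error potential (EP)      = 4.157735
```

The overlap of 12 sits 6 cells above independence while one null
standard deviation is `σ₀ ≈ 1.842`, so `EP = 6 − 1.842 ≈ 4.158 > 0`:
the co-occurrence is significant and the pair would form an edge.

## Worked example: end-to-end selection

The bundled benchmark generates a branching-trajectory dataset in the
regime where housekeeping genes dwarf the state markers in expression
(non-zero means ≈ 115 vs ≈ 1.74) — the regime where variance-based
selection fails outright:

```python
import cesfw.benchmark as bm
from cesfw import RunConfig, run_pipeline

ds = bm.simulate_dataset(bm.preset("sd2", seed=0))
result = run_pipeline(ds.counts, RunConfig(top_k=100))
print("top 10 selected genes:", result.selected_genes[:10])
precision = (ds.gene_truth.loc[result.selected_genes] == "TF").mean()
print(f"TF precision in top 100: {precision:.2f}")
```

Output:

```
top 10 selected genes: ['TF_s4_003', 'TF_s4_015', 'TF_s4_012', 'TF_s4_023', 'TF_s4_020', 'TF_s4_014', 'TF_s4_002', 'TF_s4_011', 'TF_s4_018', 'TF_s4_001']
TF precision in top 100: 0.93
```

All ten leading genes are true state markers despite being ~65× more
weakly expressed than the housekeeping background.  On the same data a
log-variance ranking achieves AUROC 0 (it ranks every housekeeping
gene above every marker).

## Command line

The `cesfw` entry point wraps the library:

```bash
cesfw run counts.tsv --out-prefix results/run      # full workflow
cesfw benchmark --preset sd4 --seeds 3 --out results/bench
cesfw markers counts.tsv --target-cells-file target.txt --out markers.tsv
```

See `cesfw --help` for the full subcommand list
(`normalize`, `exclude-batch`, `matrices`, `weights`, `select`,
`markers`, `cooccurrence`, `benchmark`, `run`).

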