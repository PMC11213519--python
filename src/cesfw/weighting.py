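"""cESFW feature weights: EP-gated weighted node centrality with an
edge-count penalty.

The ESS matrix is read as a weighted undirected gene graph and dEPs
(EP clipped below at zero) as per-edge significance weights.  A gene's
centrality is the dEPs-weighted column average of its ESS values;
its weight then divides the centrality by a slowly growing function of
its significant-edge count, encoding the assumption that cell identity
is governed by relatively small networks of tightly co-expressed genes
rather than by broadly connected hub genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ESMatrices

__all__ = ["weighted_node_centrality", "compute_feature_weights"]

_PENALTIES = {
    "log2": lambda e: np.log2(e + 2.0),
    "linear": lambda e: e + 1.0,
    "none": lambda e: np.ones_like(e, dtype=float),
}


def weighted_node_centrality(es: ESMatrices) -> pd.Series:
    """Centrality c_j = sum_i dEPs[i,j] ESS[i,j] / sum_i dEPs[i,j].

    The diagonal is excluded; genes with no significant edge (zero
    denominator) get centrality 0.  Partners are summed in canonical
    (sorted-gene-id) order so the result is bit-identical no matter how
    the input columns are ordered.
    """
    ess = es.ess.to_numpy(dtype=float).copy()
    deps = es.deps.to_numpy(dtype=float).copy()
    np.fill_diagonal(ess, 0.0)
    np.fill_diagonal(deps, 0.0)
    row_order = np.argsort(es.ess.index.to_numpy(), kind="mergesort")
    num = (deps[row_order] * ess[row_order]).sum(axis=0)
    den = deps[row_order].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return pd.Series(c, index=es.gene_ids, name="centrality")


def compute_feature_weights(es: ESMatrices, penalty: str = "log2") -> pd.DataFrame:
    """Build the per-gene feature-weight table.

    Columns: ``centrality``, ``edge_count`` (strictly positive
    off-diagonal dEPs entries in the gene's column), ``weight``
    (= centrality / penalty(edge_count)) and ``rank`` (1 = highest
    weight, ties broken by gene id).
    """
    if penalty not in _PENALTIES:
        raise ValueError(f"unknown penalty {penalty!r}")
    c = weighted_node_centrality(es)
    deps = es.deps.to_numpy(dtype=float).copy()
    np.fill_diagonal(deps, 0.0)
    e = (deps > 0).sum(axis=0)
    w = c.to_numpy() / _PENALTIES[penalty](e.astype(float))
    w = np.where(e == 0, 0.0, w)
    table = pd.DataFrame(
        {
            "centrality": c.to_numpy(),
            "edge_count": e,
            "weight": w,
        },
        index=es.gene_ids,
    )
    # stable tie-break on gene id: sort by id first, then stably by weight
    order = table.sort_index(kind="mergesort").sort_values(
        "weight", ascending=False, kind="mergesort"
    )
    table["rank"] = pd.Series(
        np.arange(1, len(table) + 1), index=order.index
    ).reindex(table.index)
    return table
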