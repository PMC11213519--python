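"""Exclusion of genes significantly enriched within a single dataset.

When several scRNA-seq datasets are merged, genes whose expression
tracks one dataset of origin contribute batch effects.  Each dataset is
encoded as a binary cell-membership indicator, minority-oriented
exactly like a gene, and every gene's activity vector is entropy-sorted
against every indicator.  A gene is excluded when, for some dataset,
EP > 0 (co-occurrence beyond random chance) and its ESS against that
dataset's indicator reaches the configured effect-size threshold.
Only positive enrichment triggers exclusion; depletion does not.

Caveat surfaced in the report rather than resolved: a cell type
genuinely exclusive to one dataset will look exactly like a batch
effect to this test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ActivityMatrix
from .config import RunConfig
from . import es_core
from .activity import minority_orient

__all__ = ["BatchExclusionReport", "find_batch_enriched_genes"]


@dataclass
class BatchExclusionReport:
    excluded_genes: list
    evidence: pd.DataFrame  # rows: excluded genes; cols: dataset_label, ess, ep
    ess_threshold: float
    ep_z: float
    note: str = (
        "genes exclusive to a dataset-specific cell type are "
        "indistinguishable from batch-effect genes by this test"
    )
    warnings_: list = field(default_factory=list)


def find_batch_enriched_genes(
    act: ActivityMatrix,
    dataset_labels: pd.Series,
    config: RunConfig | None = None,
) -> BatchExclusionReport:
    """Score every gene against every dataset indicator; flag enriched genes.

    ``dataset_labels`` maps cell id -> dataset of origin and must cover
    the activity matrix's cells.  With a single dataset the stage is a
    no-op (with a warning).
    """
    if config is None:
        config = RunConfig()
    labels = pd.Series(dataset_labels).reindex(act.cell_ids)
    if labels.isna().any():
        raise ValueError("dataset_labels must cover every cell in the matrix")
    groups = sorted(labels.unique(), key=str)
    if len(groups) < 2:
        warnings.warn("single dataset label: batch exclusion is a no-op")
        return BatchExclusionReport(
            excluded_genes=[],
            evidence=pd.DataFrame(columns=["dataset_label", "ess", "ep"]),
            ess_threshold=config.batch_ess_threshold,
            ep_z=config.ep_z,
            warnings_=["single dataset label"],
        )
    small = [g for g in groups if (labels == g).sum() < 2]
    if small:
        raise ValueError(f"datasets with < 2 cells: {small}")

    V = act.values.to_numpy(dtype=float)
    rows = {}
    for g in groups:
        indicator = (labels == g).to_numpy(dtype=float)
        indicator, _ = minority_orient(indicator)
        for gi, gene in enumerate(act.gene_ids):
            pc = es_core.make_pair(V[:, gi], indicator, 0, 1)
            ep = es_core.error_potential(pc, config.ep_z)
            if ep <= 0:
                continue
            s = es_core.ess(pc)
            if s >= config.batch_ess_threshold:
                prev = rows.get(gene)
                if prev is None or s > prev[1]:
                    rows[gene] = (g, s, ep)
    evidence = pd.DataFrame(
        [(gene, *vals) for gene, vals in rows.items()],
        columns=["gene_id", "dataset_label", "ess", "ep"],
    ).set_index("gene_id")
    excluded = sorted(rows, key=str)
    return BatchExclusionReport(
        excluded_genes=excluded,
        evidence=evidence.sort_index(),
        ess_threshold=config.batch_ess_threshold,
        ep_z=config.ep_z,
    )
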