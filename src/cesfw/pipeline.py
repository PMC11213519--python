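"""The cESFW workflow as one pure function of (counts, config).

Stage order: QC + activity normalisation -> optional dataset-enrichment
exclusion -> pairwise ESS/EP matrices -> feature weights -> top-k
selection.  All randomness downstream (embedding) flows from the single
seed in the config; the stages here are fully deterministic, so
repeated runs on the same inputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .containers import ActivityMatrix, CountsMatrix, ESMatrices
from .config import RunConfig
from .activity import build_activity_matrix
from .batch import BatchExclusionReport, find_batch_enriched_genes
from .es_core import pairwise_matrices
from .selection import select_top_k
from .weighting import compute_feature_weights

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    activity: ActivityMatrix
    batch_report: BatchExclusionReport | None
    es: ESMatrices
    weights: "object"  # FeatureWeightTable (pandas DataFrame)
    selected_genes: list


def run_pipeline(
    counts: CountsMatrix,
    config: RunConfig | None = None,
    exclude_batch: bool = True,
) -> PipelineResult:
    """Run the full feature-selection workflow on a counts matrix.

    Batch exclusion runs only when the metadata carries more than one
    ``dataset_label``; disabling it (or presenting a single dataset)
    yields identical weights.
    """
    if config is None:
        config = RunConfig()
    stage = "validation"
    try:
        counts.validate()

        stage = "activity_normalization"
        act = build_activity_matrix(counts, config)
        logger.info("activity matrix: %d cells x %d genes", *act.values.shape)

        stage = "batch_exclusion"
        report = None
        labels = counts.cell_meta.get("dataset_label")
        if exclude_batch and labels is not None and labels.nunique() > 1:
            report = find_batch_enriched_genes(act, labels, config)
            if report.excluded_genes:
                keep = [g for g in act.gene_ids if g not in set(report.excluded_genes)]
                act = act.subset_genes(keep)
                logger.info(
                    "excluded %d dataset-enriched genes", len(report.excluded_genes)
                )

        stage = "es_matrices"
        es = pairwise_matrices(act, config)

        stage = "feature_weighting"
        weights = compute_feature_weights(es, config.penalty)

        stage = "selection"
        k = min(config.top_k, len(weights))
        selected = select_top_k(weights, k)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return PipelineResult(
        activity=act,
        batch_report=report,
        es=es,
        weights=weights,
        selected_genes=selected,
    )
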