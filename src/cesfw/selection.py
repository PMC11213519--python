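"""Gene selection and sample embedding.

``select_top_k`` takes the highest-weighted genes.  The selected set is
then characterised in ESS space: hierarchical clustering of the rows of
the selected ESS submatrix (correlation distance, average linkage)
partitions the genes, and clusters whose mean centrality stands far
above the rest are flagged as high-centrality hubs — empirically these
carry generic transcription/translation/metabolism signal and removing
them sharpens the embedding.  The final keep/drop choice is the user's;
this module only computes and flags.

``embed_and_cluster_samples`` is thin glue over umap-learn and
scikit-learn with the default parameters: UMAP(n_neighbors=50,
min_dist=0.1, metric="correlation") and agglomerative clustering with
correlation distance, run directly on the counts subset to the selected
genes — no smoothing, clipping or other transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_samples

from .containers import CountsMatrix, ESMatrices
from .config import RunConfig

__all__ = [
    "select_top_k",
    "GeneClusterPartition",
    "partition_gene_clusters",
    "embed_and_cluster_samples",
]


def select_top_k(table: pd.DataFrame, k: int) -> list:
    """The k highest-weight genes from a feature-weight table.

    Deterministic under the table's rank (ties already broken by gene
    id when the table was built).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    return list(table.sort_values("rank").index[:k])


@dataclass
class GeneClusterPartition:
    labels: pd.Series  # gene -> cluster id
    summary: pd.DataFrame  # per cluster: size, mean_centrality, mean_edge_count, is_high_centrality_hub


def partition_gene_clusters(
    es: ESMatrices,
    table: pd.DataFrame,
    n_gene_clusters: int = 2,
    hub_centrality_factor: float = 1.5,
) -> GeneClusterPartition:
    """Cluster selected genes on correlation distance between ESS rows.

    Agglomerative (average linkage).  A cluster is flagged as a
    high-centrality hub when its mean centrality exceeds
    ``hub_centrality_factor`` times the median of the cluster means
    (never with a single cluster).
    """
    genes = list(es.gene_ids)
    if len(genes) < n_gene_clusters:
        raise ValueError("fewer selected genes than requested clusters")
    X = es.ess.to_numpy(dtype=float)
    degenerate = X.std(axis=1) == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant ESS rows; they join their "
            "nearest cluster by mean-offset distance"
        )
        # tiny jitter-free fallback: constant rows get zero correlation
        # distance to each other and maximal to the rest via nan -> 1
    if n_gene_clusters == 1:
        labels = np.ones(len(genes), dtype=int)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = pdist(X, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)
        labels = fcluster(linkage(d, method="average"), n_gene_clusters, "maxclust")
    lab = pd.Series(labels, index=genes, name="gene_cluster")
    rows = []
    for cid, members in lab.groupby(lab):
        idx = members.index
        rows.append(
            {
                "cluster": cid,
                "size": len(idx),
                "mean_centrality": float(table.loc[idx, "centrality"].mean()),
                "mean_edge_count": float(table.loc[idx, "edge_count"].mean()),
            }
        )
    summary = pd.DataFrame(rows).set_index("cluster")
    if len(summary) > 1:
        med = summary["mean_centrality"].median()
        summary["is_high_centrality_hub"] = (
            summary["mean_centrality"] > hub_centrality_factor * med
        )
    else:
        summary["is_high_centrality_hub"] = False
    return GeneClusterPartition(labels=lab, summary=summary)


def embed_and_cluster_samples(
    counts: CountsMatrix,
    selected_genes,
    config: RunConfig | None = None,
) -> dict:
    """UMAP embedding + agglomerative clustering of cells on the
    selected-gene expression, with per-cluster mean silhouettes
    (correlation distance).

    Returns ``{"embedding": DataFrame, "cluster_labels": Series,
    "silhouette": Series}``; the silhouette entry is None when a single
    cluster covers all cells (undefined).
    """
    import umap

    if config is None:
        config = RunConfig()
    X = counts.values.loc[:, list(selected_genes)].to_numpy(dtype=float)
    n = X.shape[0]
    if n < config.umap_neighbors + 1:
        raise ValueError(
            f"{n} cells < umap_neighbors+1 ({config.umap_neighbors + 1}); "
            "lower umap_neighbors"
        )
    reducer = umap.UMAP(
        n_neighbors=config.umap_neighbors,
        min_dist=config.umap_min_dist,
        metric="correlation",
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(X)
    embedding = pd.DataFrame(
        coords, index=counts.cell_ids, columns=["umap1", "umap2"]
    )
    k = min(config.n_sample_clusters, n)
    clusterer = AgglomerativeClustering(
        n_clusters=k, metric="correlation", linkage="average"
    )
    labels = pd.Series(clusterer.fit_predict(X), index=counts.cell_ids, name="cluster")
    sil = cluster_silhouettes(X, labels)
    return {"embedding": embedding, "cluster_labels": labels, "silhouette": sil}


def cluster_silhouettes(X: np.ndarray, labels: pd.Series) -> pd.Series | None:
    """Per-cluster mean silhouette on correlation distance; None when
    fewer than two clusters are present (silhouette undefined)."""
    if labels.nunique() < 2:
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        s = silhouette_samples(X, labels.to_numpy(), metric="correlation")
    return pd.Series(s, index=labels.index).groupby(labels).mean()
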