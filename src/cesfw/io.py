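"""Readers and writers for the formats the workflow touches.

MatrixMarket triplets travel with ``barcodes.tsv`` / ``features.tsv``
side files (cellranger convention, gene-major on disk); dense matrices
as tab- or comma-delimited text with cell rows and gene columns
(transposed inputs via a flag).  Outputs are tab-delimited.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountsMatrix, ValidationError

__all__ = ["read_counts", "write_counts", "write_ranked_genes", "read_ranked_genes"]


def _attach_meta(values: pd.DataFrame, meta_path) -> pd.DataFrame:
    if meta_path is None:
        return pd.DataFrame(index=values.index)
    meta = pd.read_csv(meta_path, sep=None, engine="python", index_col=0)
    meta.index = meta.index.astype(str)
    missing = values.index.difference(meta.index)
    if len(missing):
        raise ValidationError(
            f"metadata missing for {len(missing)} cells, e.g. {list(missing[:3])}"
        )
    return meta.reindex(values.index)


def read_counts(
    path,
    format: str = "delimited",
    genes_as_rows: bool = False,
    meta_path=None,
) -> CountsMatrix:
    """Read a counts matrix.

    ``format="mtx_triplet"``: ``path`` is the ``.mtx`` file; barcode and
    feature side files (``barcodes.tsv``, ``features.tsv`` or
    ``genes.tsv``) must sit next to it; the matrix is gene-major on disk
    (genes x cells) per convention.  ``format="delimited"``: dense
    tab/comma-delimited text, cells x genes unless ``genes_as_rows``.
    """
    path = Path(path)
    if format == "mtx_triplet":
        try:
            mat = spio.mmread(path)
        except ValueError as exc:
            raise ValidationError(f"malformed MatrixMarket file {path}: {exc}") from exc
        barcodes_file = path.parent / "barcodes.tsv"
        features_file = path.parent / "features.tsv"
        if not features_file.exists():
            features_file = path.parent / "genes.tsv"
        if not barcodes_file.exists() or not features_file.exists():
            raise FileNotFoundError(
                f"barcodes.tsv and features.tsv/genes.tsv must sit next to {path}"
            )
        barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str)
        features = pd.read_csv(features_file, sep="\t", header=None)[0].astype(str)
        dense = np.asarray(sparse.coo_matrix(mat).todense(), dtype=float)
        # disk convention is genes x cells
        values = pd.DataFrame(dense.T, index=barcodes, columns=features)
    elif format == "delimited":
        values = pd.read_csv(path, sep=None, engine="python", index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        if genes_as_rows:
            values = values.T
        values = values.astype(float)
    else:
        raise ValueError(f"unknown format {format!r}")
    return CountsMatrix(values, _attach_meta(values, meta_path))


def write_counts(counts: CountsMatrix, path, format: str = "delimited") -> None:
    """Inverse of :func:`read_counts` for the two supported formats."""
    path = Path(path)
    if format == "delimited":
        counts.values.to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        path.parent.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path.with_suffix(".mtx"), sparse.coo_matrix(counts.values.to_numpy().T))
        pd.Series(counts.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(counts.gene_ids).to_csv(
            path.parent / "features.tsv", sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(counts.cell_meta.columns):
        counts.cell_meta.to_csv(Path(str(path) + ".meta.tsv"), sep="\t")


def write_ranked_genes(table: pd.DataFrame, path) -> None:
    """Write a feature-weight table as tab-delimited text, rank order.

    Columns: gene_id, centrality, edge_count, weight, rank.  Weight ties
    were already broken by gene id when ranks were assigned.
    """
    if len(table) == 0:
        raise ValueError("empty feature-weight table")
    out = table.sort_values("rank").reset_index(names="gene_id")
    out = out[["gene_id", "centrality", "edge_count", "weight", "rank"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ranked_genes(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t").set_index("gene_id")
    return table
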