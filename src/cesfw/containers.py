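"""In-memory containers shared across the cESFW workflow.

All matrices are oriented cells x genes. Values travel as pandas
DataFrames so that gene and cell identifiers stay attached to the
numbers through every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input matrix violates a container invariant."""


@dataclass
class CountsMatrix:
    """Raw (or pre-normalised) expression values, cells x genes.

    ``cell_meta`` is indexed by cell id and may carry ``dataset_label``,
    ``embryo_id`` and ``state_label`` columns; absent columns are
    treated as missing metadata, not errors.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.cell_meta is None or len(self.cell_meta) == 0:
            self.cell_meta = pd.DataFrame(index=self.values.index)
        self.validate()

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        dup_genes = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_genes):
            raise ValidationError(
                f"duplicate gene ids: {sorted(map(str, dup_genes))}"
            )
        dup_cells = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_cells):
            raise ValidationError(
                f"duplicate cell ids: {sorted(map(str, dup_cells))}"
            )
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValidationError("counts matrix contains negative values")
        if not self.cell_meta.index.equals(self.values.index):
            raise ValidationError("cell_meta index does not match cell ids")

    def subset_genes(self, genes) -> "CountsMatrix":
        return CountsMatrix(self.values.loc[:, list(genes)], self.cell_meta)


@dataclass
class ActivityMatrix:
    """Minority-state feature activity matrix M_m (cells x genes, in [0,1]).

    ``flip_flags[g]`` is True when gene g was complemented (1 - v) so its
    activity mass lies in the minority of samples.  ``scale_factors[g]``
    is the percentile divisor used to map counts into [0,1].
    """

    values: pd.DataFrame
    flip_flags: pd.Series
    scale_factors: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def cardinalities(self) -> pd.Series:
        """Per-gene minority cardinality: the column sum of activities."""
        return self.values.sum(axis=0)

    def subset_genes(self, genes) -> "ActivityMatrix":
        genes = list(genes)
        return ActivityMatrix(
            self.values.loc[:, genes],
            self.flip_flags.loc[genes],
            self.scale_factors.loc[genes],
        )


@dataclass
class ESMatrices:
    """Symmetric gene x gene ESS and EP matrices plus the gated dEPs.

    ``deps`` is ``ep`` with negative entries (and the diagonal) zeroed:
    the significance weights for node centrality.
    """

    ess: pd.DataFrame
    ep: pd.DataFrame
    deps: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.ess.columns

    def subset_genes(self, genes) -> "ESMatrices":
        genes = list(genes)
        return ESMatrices(
            self.ess.loc[genes, genes],
            self.ep.loc[genes, genes],
            self.deps.loc[genes, genes],
        )
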