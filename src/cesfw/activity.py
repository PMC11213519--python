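"""Temporary minority-state normalisation.

Each gene is mapped into [0, 1] by dividing by the p-th percentile of
its strictly positive values (values above the percentile saturate at
1), then complemented (v -> 1 - v) whenever the resulting activity mass
exceeds half the samples, so every gene's activity describes its
*minority* state.  The raw counts themselves are never altered — this
matrix (M_m) exists only so pairs of genes can be entropy-sorted on a
common scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ActivityMatrix, CountsMatrix
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["percentile_scale", "minority_orient", "build_activity_matrix"]


class DegenerateGeneError(ValueError):
    """An all-zero gene cannot be percentile-scaled."""


def percentile_scale(
    gene_values: np.ndarray, p: float = 97.5, on_positive: bool = True
) -> tuple[np.ndarray, float]:
    """Scale a gene's values into [0, 1] by its p-th percentile.

    The percentile is taken over the strictly positive entries (the
    default; with sparse data the percentile over all entries is often
    zero).  Values above the percentile clip to 1.  Returns the scaled
    vector and the divisor used.

    The percentile is the ``lower`` order statistic rather than an
    interpolated value: the divisor is then an actual data point, which
    makes the scaled vector exactly invariant to any positive rescaling
    of the input that is itself exact in floating point (e.g. integer
    counts times an integer).
    """
    v = np.asarray(gene_values, dtype=float)
    pos = v[v > 0]
    if pos.size == 0:
        raise DegenerateGeneError("all-zero gene vector")
    base = pos if on_positive else v
    s = float(np.percentile(base, p, method="lower"))
    if s <= 0:
        s = float(pos.max())
    return np.minimum(v / s, 1.0), s


def minority_orient(scaled: np.ndarray) -> tuple[np.ndarray, bool]:
    """Complement the vector when its activity mass is the majority.

    If sum(scaled) > n/2 the gene's high-activity state is the majority
    state, so each value is deducted from 1.  An exact tie (sum = n/2)
    is left unflipped; the ESS is invariant to the choice in that
    symmetric case.
    """
    scaled = np.asarray(scaled, dtype=float)
    if scaled.sum() > scaled.size / 2.0:
        return 1.0 - scaled, True
    return scaled, False


def build_activity_matrix(counts: CountsMatrix, config: RunConfig | None = None) -> ActivityMatrix:
    """Convert a counts matrix into its minority-state activity matrix.

    Genes expressed in fewer than ``config.min_cells_expressing`` cells
    are dropped (and logged) before scaling.
    """
    if config is None:
        config = RunConfig()
    counts.validate()
    # canonical cell order: downstream sums then accumulate in an order
    # independent of how the input rows were arranged, so results are
    # bit-identical under cell permutation
    cell_order = counts.cell_ids.sort_values()
    values_df = counts.values.loc[cell_order]
    V = values_df.to_numpy(dtype=float)
    expressing = (V > 0).sum(axis=0)
    keep = expressing >= config.min_cells_expressing
    dropped = counts.gene_ids[~keep]
    if len(dropped):
        logger.info(
            "dropping %d genes expressed in < %d cells: %s",
            len(dropped),
            config.min_cells_expressing,
            ", ".join(map(str, dropped[:20])) + ("..." if len(dropped) > 20 else ""),
        )
    if not keep.any():
        raise DegenerateGeneError("no genes survive the expression filter")
    V = V[:, keep]
    genes = counts.gene_ids[keep]

    values = np.empty_like(V)
    scales = np.empty(V.shape[1])
    flips = np.empty(V.shape[1], dtype=bool)
    for g in range(V.shape[1]):
        scaled, s = percentile_scale(
            V[:, g], config.percentile_p, config.percentile_on_positive
        )
        oriented, flipped = minority_orient(scaled)
        values[:, g] = oriented
        scales[g] = s
        flips[g] = flipped
    return ActivityMatrix(
        values=pd.DataFrame(values, index=cell_order, columns=genes),
        flip_flags=pd.Series(flips, index=genes, name="flipped"),
        scale_factors=pd.Series(scales, index=genes, name="scale"),
    )
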