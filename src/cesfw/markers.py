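"""ESS-based downstream statistics.

The Entropy Sort Score doubles as a marker statistic: because it
declines whenever a gene's activity is observed outside the population
of interest, ranking genes by ESS against a cell-state indicator
favours genes expressed specifically in that state rather than genes
merely up-regulated there.  This module provides that ranking, its
progressive lineage-restricted form, the per-embryo cell-state
co-occurrence matrix, pseudobulk correlation distances, and kNN label
transfer in embedding space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier

from .containers import ActivityMatrix, CountsMatrix
from .activity import minority_orient, percentile_scale
from . import es_core

__all__ = [
    "ess_marker_ranking",
    "staged_lineage_ranking",
    "CooccurrenceMatrix",
    "embryo_cooccurrence",
    "pseudobulk_correlation",
    "knn_label_transfer",
]


def _ess_against_indicator(
    act: ActivityMatrix, indicator: np.ndarray, binarize: bool = False
) -> pd.Series:
    V = act.values.to_numpy(dtype=float)
    if binarize:
        V = (V > 0).astype(float)
    scores = np.empty(V.shape[1])
    for g in range(V.shape[1]):
        pc = es_core.make_pair(V[:, g], indicator, 0, 1)
        scores[g] = es_core.ess(pc)
    return pd.Series(scores, index=act.gene_ids, name="ess")


def ess_marker_ranking(
    act: ActivityMatrix, target_cells, binarize: bool = False
) -> pd.DataFrame:
    """Rank genes by signed ESS against a cell-subset indicator.

    ``target_cells`` is a non-empty proper subset of the matrix's
    cells.  The indicator is minority-oriented before scoring.  With
    ``binarize`` the gene activities are reduced to presence/absence
    for comparability with discrete entropy sorting.
    """
    target = pd.Index(target_cells)
    missing = target.difference(act.cell_ids)
    if len(missing):
        raise ValueError(f"unknown cells in target: {list(missing)[:5]}")
    if len(target) == 0:
        raise ValueError("empty target subset")
    if len(target) == act.n_cells:
        raise ValueError("target covers all cells; ESS against it is undefined")
    indicator = act.cell_ids.isin(target).astype(float)
    indicator, _ = minority_orient(indicator)
    scores = _ess_against_indicator(act, indicator, binarize=binarize)
    out = scores.sort_values(ascending=False, kind="mergesort").to_frame()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def staged_lineage_ranking(
    act: ActivityMatrix,
    annotations: pd.Series,
    nested_populations: list,
    binarize: bool = False,
    top_n: int = 30,
) -> list[dict]:
    """One ESS marker ranking per stage of a progressively restricted
    lineage.

    ``nested_populations`` is an ordered list of cell-state label sets,
    each a strict superset of the next (broadest stage first, e.g.
    morula+branch+ICM+Epi → ... → Epi alone).  Returns, per stage, the
    full ranking and its top ``top_n`` genes (the manual-inspection
    window).
    """
    sets = [set(p) for p in nested_populations]
    for i in range(len(sets) - 1):
        if not sets[i] > sets[i + 1]:
            raise ValueError(
                f"stage {i + 1} ({sorted(sets[i + 1])}) is not a strict "
                f"subset of stage {i} ({sorted(sets[i])})"
            )
    ann = pd.Series(annotations).reindex(act.cell_ids)
    results = []
    for stage, states in enumerate(sets):
        cells = ann.index[ann.isin(states)]
        ranking = ess_marker_ranking(act, cells, binarize=binarize)
        results.append(
            {
                "stage": stage,
                "states": sorted(states),
                "ranking": ranking,
                "top": list(ranking.index[:top_n]),
            }
        )
    return results


@dataclass
class CooccurrenceMatrix:
    ess: pd.DataFrame  # state x state
    embryo_count: int
    states: list


def embryo_cooccurrence(cell_meta: pd.DataFrame) -> CooccurrenceMatrix:
    """ESS co-occurrence of cell states across individual embryos.

    Each embryo is one sample; its feature vector is the per-state cell
    count divided by the embryo's total cell count.  Each state column
    is then treated exactly like a gene (max scaling + minority
    orientation) and states are scored pairwise by ESS.
    """
    meta = cell_meta.dropna(subset=["embryo_id", "state_label"])
    dropped = len(cell_meta) - len(meta)
    if dropped:
        warnings.warn(f"dropped {dropped} cells lacking embryo or state label")
    comp = (
        meta.groupby(["embryo_id", "state_label"]).size().unstack(fill_value=0)
    )
    comp = comp.loc[comp.sum(axis=1) > 0]
    if comp.shape[0] < 2 or comp.shape[1] < 2:
        raise ValueError("need at least 2 embryos and 2 states")
    frac = comp.div(comp.sum(axis=1), axis=0).to_numpy(dtype=float)
    cols = []
    for j in range(frac.shape[1]):
        scaled, _ = percentile_scale(frac[:, j], p=100)
        oriented, _ = minority_orient(scaled)
        cols.append(oriented)
    M = np.column_stack(cols)
    k = M.shape[1]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            pc = es_core.make_pair(M[:, i], M[:, j], i, j)
            out[i, j] = out[j, i] = es_core.ess(pc)
    states = list(comp.columns)
    return CooccurrenceMatrix(
        ess=pd.DataFrame(out, index=states, columns=states),
        embryo_count=comp.shape[0],
        states=states,
    )


def pseudobulk_correlation(
    counts: CountsMatrix, selected_genes, state_labels: pd.Series
) -> pd.DataFrame:
    """State x state correlation distance (1 - Pearson r) between
    per-state mean expression vectors over the selected genes.

    Low distances indicate similar states.  A state whose pseudobulk
    vector is constant has undefined correlation and is reported as
    missing (NaN).
    """
    X = counts.values.loc[:, list(selected_genes)]
    labels = pd.Series(state_labels).reindex(counts.cell_ids)
    if labels.isna().any():
        raise ValueError("state_labels must cover every cell")
    pseudo = X.groupby(labels).mean()
    P = pseudo.to_numpy(dtype=float)
    sd = P.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(P)
    d = 1.0 - r
    d[sd == 0, :] = np.nan
    d[:, sd == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pseudo.index, columns=pseudo.index)


def knn_label_transfer(
    reference_coords: pd.DataFrame,
    reference_labels: pd.Series,
    query_coords: pd.DataFrame,
    k: int = 20,
    query_conditions: pd.Series | None = None,
) -> dict:
    """Majority-vote kNN label transfer in embedding space.

    A classifier with ``k`` neighbours (Euclidean in the low-dimensional
    embedding) is fitted on the reference and applied to the query.
    Ties break toward the smaller label (scikit-learn's class ordering).
    Returns predicted labels and, when ``query_conditions`` is given,
    the per-condition proportion of each predicted state.
    """
    if k > len(reference_coords):
        raise ValueError(f"k={k} exceeds reference size {len(reference_coords)}")
    clf = KNeighborsClassifier(n_neighbors=k)
    labels = pd.Series(reference_labels).reindex(reference_coords.index)
    clf.fit(reference_coords.to_numpy(dtype=float), labels.to_numpy())
    pred = pd.Series(
        clf.predict(query_coords.to_numpy(dtype=float)),
        index=query_coords.index,
        name="predicted_label",
    )
    proportions = None
    if query_conditions is not None:
        cond = pd.Series(query_conditions).reindex(query_coords.index)
        proportions = (
            pd.crosstab(cond, pred, normalize="index")
            .sort_index()
            .sort_index(axis=1)
        )
    return {"predicted_labels": pred, "proportions": proportions}
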