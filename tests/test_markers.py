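import numpy as np
import pandas as pd
import pytest

from cesfw import (
    CountsMatrix,
    embryo_cooccurrence,
    ess_marker_ranking,
    knn_label_transfer,
    pseudobulk_correlation,
    staged_lineage_ranking,
)

from conftest import binary_activity


class TestMarkerRanking:
    def test_specific_marker_outranks_leaky_gene(self, rng):
        """At equal expression frequency (30 cells each) the gene whose
        expression stays inside the target population outranks the gene
        that leaks outside it."""
        n = 120
        target = np.arange(n) < 50
        V = np.zeros((n, 3))
        V[:30, 0] = 1.0  # 30 cells, all inside the target
        V[:25, 1] = 1.0  # 30 cells, 5 of them leak outside
        V[50:55, 1] = 1.0
        V[:, 2] = (rng.random(n) < 0.3).astype(float)  # unrelated
        act = binary_activity(V)
        cells = act.cell_ids[target]
        table = ess_marker_ranking(act, cells)
        assert table.index[0] == "g000"
        assert table.loc["g000", "ess"] == pytest.approx(1.0)
        assert table.loc["g000", "ess"] > table.loc["g001", "ess"]
        assert table.loc["g001", "ess"] > table.loc["g002", "ess"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_empty_and_full_targets_rejected(self, binary_fixture_50):
        with pytest.raises(ValueError):
            ess_marker_ranking(binary_fixture_50, [])
        with pytest.raises(ValueError):
            ess_marker_ranking(binary_fixture_50, list(binary_fixture_50.cell_ids))

    def test_unknown_cells_rejected(self, binary_fixture_50):
        with pytest.raises(ValueError, match="unknown cells"):
            ess_marker_ranking(binary_fixture_50, ["nope"])

    def test_binarize_reduces_to_presence_absence(self, rng):
        n = 80
        target = np.arange(n) < 20
        graded = np.where(target, rng.uniform(0.3, 1.0, n), 0.0)
        act = binary_activity(np.column_stack([graded]))
        cells = act.cell_ids[target]
        table = ess_marker_ranking(act, cells, binarize=True)
        assert table.loc["g000", "ess"] == pytest.approx(1.0)


class TestStagedLineage:
    def test_progressive_restriction(self, small_counts, rng):
        from cesfw import build_activity_matrix

        act = build_activity_matrix(small_counts)
        ann = small_counts.cell_meta["state_label"]
        results = staged_lineage_ranking(
            act, ann, [{"A", "B"}, {"A"}], top_n=5
        )
        assert [r["stage"] for r in results] == [0, 1]
        # at the A-only stage the module-1 genes (planted in state A) lead
        top = results[1]["top"]
        assert all(g.startswith("m1_") for g in top)
        assert len(top) == 5

    def test_non_nested_stages_rejected(self, small_counts):
        from cesfw import build_activity_matrix

        act = build_activity_matrix(small_counts)
        ann = small_counts.cell_meta["state_label"]
        with pytest.raises(ValueError, match="strict"):
            staged_lineage_ranking(act, ann, [{"A"}, {"A", "B"}])
        with pytest.raises(ValueError, match="strict"):
            staged_lineage_ranking(act, ann, [{"A"}, {"A"}])


def _meta(embryos, states):
    return pd.DataFrame(
        {"embryo_id": embryos, "state_label": states},
        index=[f"c{i}" for i in range(len(embryos))],
    )


class TestEmbryoCooccurrence:
    def test_worked_micro_example(self):
        """3 embryos x 3 states with counts [[2,1,0],[0,3,1],[4,0,0]].

        Frozen from an independent hand computation: after composition
        normalisation, max scaling and minority orientation, every state
        pair lands on an attained overlap bound, so all pairwise ESS
        values are exactly 1."""
        comp = [[2, 1, 0], [0, 3, 1], [4, 0, 0]]
        embryos, states = [], []
        for e, row in enumerate(comp):
            for s, k in enumerate(row):
                embryos += [f"e{e}"] * k
                states += [f"s{s}"] * k
        out = embryo_cooccurrence(_meta(embryos, states))
        assert out.embryo_count == 3
        assert out.states == ["s0", "s1", "s2"]
        assert np.allclose(out.ess.to_numpy(), np.ones((3, 3)))

    def test_cooccurring_one_and_exclusive_minus_one(self):
        # 6 embryos: states X and Y always appear together in the same
        # embryos; state Z only in the others.
        embryos, states = [], []
        for e in range(3):
            embryos += [f"co{e}"] * 4
            states += ["X", "X", "Y", "Y"]
        for e in range(3):
            embryos += [f"ex{e}"] * 2
            states += ["Z", "Z"]
        out = embryo_cooccurrence(_meta(embryos, states))
        assert out.ess.loc["X", "Y"] == pytest.approx(1.0)
        assert out.ess.loc["X", "Z"] == pytest.approx(-1.0)
        assert out.ess.loc["Y", "Z"] == pytest.approx(-1.0)

    def test_invariant_to_cell_order_and_duplication(self):
        embryos = ["e0"] * 3 + ["e1"] * 3 + ["e2"] * 2 + ["e3"] * 2
        states = ["A", "A", "B", "A", "B", "B", "A", "A", "B", "B"]
        base = embryo_cooccurrence(_meta(embryos, states))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(embryos))
        shuffled = embryo_cooccurrence(
            _meta([embryos[i] for i in perm], [states[i] for i in perm])
        )
        assert base.ess.equals(shuffled.ess)
        # duplicating every cell changes no composition fractions
        doubled = embryo_cooccurrence(_meta(embryos * 2, states * 2))
        assert np.allclose(base.ess.to_numpy(), doubled.ess.to_numpy())

    def test_missing_labels_dropped_with_warning(self):
        meta = _meta(["e0", "e0", "e1", "e1"], ["A", "B", "A", "B"])
        meta.loc["c0", "embryo_id"] = np.nan
        with pytest.warns(UserWarning, match="dropped 1"):
            embryo_cooccurrence(meta)

    def test_too_few_embryos_rejected(self):
        with pytest.raises(ValueError):
            embryo_cooccurrence(_meta(["e0"] * 4, ["A", "A", "B", "B"]))


def _counts_with_states(X, states):
    values = pd.DataFrame(
        np.asarray(X, dtype=float),
        index=[f"c{i}" for i in range(len(X))],
        columns=[f"g{i}" for i in range(np.asarray(X).shape[1])],
    )
    meta = pd.DataFrame({"state_label": states}, index=values.index)
    return CountsMatrix(values, meta), pd.Series(states, index=values.index)


class TestPseudobulkCorrelation:
    def test_duplicate_states_have_zero_distance(self):
        X = [[1, 2, 3], [1, 2, 3], [3, 1, 0], [3, 1, 0]]
        counts, labels = _counts_with_states(X, ["A", "B", "C", "C"])
        d = pseudobulk_correlation(counts, counts.gene_ids, labels)
        assert d.loc["A", "B"] == pytest.approx(0.0)
        assert np.allclose(np.diag(d), 0.0)

    def test_anticorrelated_states_distance_two(self):
        X = [[0, 1, 2], [2, 1, 0]]
        counts, labels = _counts_with_states(X, ["A", "B"])
        d = pseudobulk_correlation(counts, counts.gene_ids, labels)
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_matches_pearson_oracle_and_affine_invariance(self, rng):
        X = rng.random((6, 10))
        counts, labels = _counts_with_states(X, list("ABCDEF"))
        d = pseudobulk_correlation(counts, counts.gene_ids, labels)
        r = np.corrcoef(X)
        expect = 1 - r
        np.fill_diagonal(expect, 0.0)
        assert np.allclose(d.to_numpy(), expect)
        # correlation distance is invariant to per-state affine maps
        X2 = 3.0 * X + 0.7
        counts2, labels2 = _counts_with_states(X2, list("ABCDEF"))
        d2 = pseudobulk_correlation(counts2, counts2.gene_ids, labels2)
        assert np.allclose(d.to_numpy(), d2.to_numpy())

    def test_constant_pseudobulk_reported_missing(self):
        X = [[2, 2, 2], [0, 1, 5]]
        counts, labels = _counts_with_states(X, ["flat", "varied"])
        d = pseudobulk_correlation(counts, counts.gene_ids, labels)
        assert np.isnan(d.loc["flat", "varied"])
        assert d.loc["flat", "flat"] == 0.0

    def test_uncovered_cells_rejected(self):
        counts, labels = _counts_with_states([[1, 2], [3, 4]], ["A", "B"])
        with pytest.raises(ValueError, match="cover"):
            pseudobulk_correlation(
                counts, counts.gene_ids, labels.iloc[:1]
            )


def _coords(points):
    return pd.DataFrame(
        np.asarray(points, dtype=float),
        index=[f"p{i}" for i in range(len(points))],
        columns=["umap1", "umap2"],
    )


class TestKnnLabelTransfer:
    def test_coincident_point_takes_reference_label(self):
        ref = _coords([[0, 0], [10, 10], [10, 11], [0, 1]])
        labels = pd.Series(["A", "B", "B", "A"], index=ref.index)
        query = _coords([[0, 0.5]])
        out = knn_label_transfer(ref, labels, query, k=2)
        assert out["predicted_labels"].iloc[0] == "A"

    def test_exact_tie_goes_to_smaller_label(self):
        ref = _coords([[-1, 0], [1, 0]])
        labels = pd.Series(["zzz", "aaa"], index=ref.index)
        query = _coords([[0, 0]])
        out = knn_label_transfer(ref, labels, query, k=2)
        assert out["predicted_labels"].iloc[0] == "aaa"

    def test_planted_clusters_transfer_cleanly(self, rng):
        n = 200
        ref = np.concatenate(
            [rng.normal(0, 0.3, (n, 2)), rng.normal(5, 0.3, (n, 2))]
        )
        labels = ["near"] * n + ["far"] * n
        query = np.concatenate(
            [rng.normal(0, 0.3, (50, 2)), rng.normal(5, 0.3, (50, 2))]
        )
        truth = np.array(["near"] * 50 + ["far"] * 50)
        conditions = pd.Series(
            ["ctrl"] * 50 + ["treat"] * 50,
            index=[f"q{i}" for i in range(100)],
        )
        out = knn_label_transfer(
            _coords(ref).set_axis([f"r{i}" for i in range(2 * n)]),
            pd.Series(labels, index=[f"r{i}" for i in range(2 * n)]),
            _coords(query).set_axis([f"q{i}" for i in range(100)]),
            k=20,
            query_conditions=conditions,
        )
        accuracy = (out["predicted_labels"].to_numpy() == truth).mean()
        assert accuracy >= 0.99
        props = out["proportions"]
        assert props.loc["ctrl", "near"] >= 0.98
        assert props.loc["treat", "far"] >= 0.98
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_k_larger_than_reference_rejected(self):
        ref = _coords([[0, 0], [1, 1]])
        labels = pd.Series(["A", "B"], index=ref.index)
        with pytest.raises(ValueError):
            knn_label_transfer(ref, labels, _coords([[0, 0]]), k=5)
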