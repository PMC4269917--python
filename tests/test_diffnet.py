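"""Edge-level comparison, enrichment, degrees, and t-statistic clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

import dimorphnet as dn


class TestEdgeDifferential:
    def test_identical_ensembles_null(self, ensemble_factory):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((6, 5))
        a = ensemble_factory(["t1", "t2"], ["g1", "g2", "g3"], scores)
        b = ensemble_factory(["t1", "t2"], ["g1", "g2", "g3"], scores.copy())
        table = dn.edge_differential(a, b)
        np.testing.assert_allclose(table["diff"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["t_stat"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p_value"], 1.0, atol=1e-9)

    def test_strong_shift_detected(self, ensemble_factory):
        rng = np.random.default_rng(1)
        base = rng.normal(0.0, 0.01, (4, 100))
        sa, sb = base.copy(), base.copy()
        sa[0] += 1.0
        sb[0] += 0.5
        a = ensemble_factory(["t"], list("wxyz"), sa)
        b = ensemble_factory(["t"], list("wxyz"), sb)
        table = dn.edge_differential(a, b)
        assert table["diff"].iloc[0] == pytest.approx(0.5, abs=0.005)
        assert table["fdr_q"].iloc[0] < 1e-5

    def test_swap_antisymmetry(self, ensemble_factory):
        rng = np.random.default_rng(2)
        a = ensemble_factory(["t"], ["g1", "g2"], rng.standard_normal((2, 6)))
        b = ensemble_factory(["t"], ["g1", "g2"], rng.standard_normal((2, 6)))
        ab = dn.edge_differential(a, b)
        ba = dn.edge_differential(b, a)
        np.testing.assert_allclose(ab["diff"], -ba["diff"], atol=1e-14)
        np.testing.assert_allclose(ab["t_stat"], -ba["t_stat"], atol=1e-12)
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-12)

    def test_small_ensemble_rejected(self, ensemble_factory):
        a = ensemble_factory(["t"], ["g"], np.ones((1, 1)))
        with pytest.raises(ValueError):
            dn.edge_differential(a, a)


class TestSelectEdges:
    def _table(self, rows):
        idx = pd.MultiIndex.from_tuples([(f"t{i}", f"g{i}") for i in range(len(rows))],
                                        names=["tf", "gene"])
        return pd.DataFrame(rows, index=idx,
                            columns=["mean_a", "mean_b", "diff", "t_stat",
                                     "p_value", "fdr_q"])

    def test_three_criteria_hand_labels(self):
        table = self._table([
            [1.0, 0.5, 0.5, 10.0, 1e-12, 1e-9],    # selected A
            [1.0, 0.9, 0.10, 5.0, 1e-12, 1e-9],    # fails diff
            [-0.2, -0.7, 0.5, 10.0, 1e-12, 1e-9],  # fails mean filter
            [0.5, 1.0, -0.5, -10.0, 1e-12, 1e-9],  # selected B
            [1.0, 0.5, 0.5, 3.0, 1e-3, 1e-2],      # fails q
        ])
        sub_a, sub_b = dn.select_sex_specific_edges(table)
        assert list(sub_a.edges.index) == [("t0", "g0")]
        assert list(sub_b.edges.index) == [("t3", "g3")]

    def test_identical_ensembles_empty(self, ensemble_factory):
        scores = np.random.default_rng(3).standard_normal((4, 5))
        a = ensemble_factory(["t1", "t2"], ["g1", "g2"], scores)
        b = ensemble_factory(["t1", "t2"], ["g1", "g2"], scores.copy())
        sub_a, sub_b = dn.select_sex_specific_edges(dn.edge_differential(a, b))
        assert len(sub_a.edges) == 0 and len(sub_b.edges) == 0

    def test_antisymmetry_of_caller(self, small_ensembles):
        ens_f, ens_m, table = small_ensembles
        sub_a, sub_b = dn.select_sex_specific_edges(table, q_max=0.05, diff_min=0.2)
        rev = dn.edge_differential(ens_m, ens_f)
        rub_a, rub_b = dn.select_sex_specific_edges(rev, q_max=0.05, diff_min=0.2)
        assert set(sub_a.edges.index) == set(rub_b.edges.index)
        assert set(sub_b.edges.index) == set(rub_a.edges.index)


class TestTargetedGeneSets:
    def _sub(self, pairs, label="A_specific"):
        idx = pd.MultiIndex.from_tuples(pairs, names=["tf", "gene"])
        return dn.SexSpecificSubnetwork(label, pd.DataFrame(index=idx))

    def test_disjoint(self):
        out = dn.targeted_gene_sets(self._sub([("t", "g1")]), self._sub([("t", "g2")]))
        assert out["counts"] == (1, 1, 0)

    def test_overlap_arithmetic(self):
        a = self._sub([("t", "g1"), ("t", "g2"), ("u", "g3")])
        b = self._sub([("t", "g2"), ("u", "g3"), ("u", "g4")], "B_specific")
        out = dn.targeted_gene_sets(a, b)
        assert out["counts"] == (1, 1, 2)
        assert out["shared"] == ["g2", "g3"]

    def test_empty(self):
        out = dn.targeted_gene_sets(self._sub([]), self._sub([]))
        assert out["counts"] == (0, 0, 0)


class TestFisherEnrichment:
    def test_exact_hypergeometric_value(self):
        universe = [f"g{i}" for i in range(20)]
        query = universe[:5]
        gene_set = universe[:3] + [universe[10]]  # overlap 3 of set size 4
        res = dn.fisher_enrichment(query, universe, {"s": gene_set})
        expect = (comb(4, 3) * comb(16, 2) + comb(4, 4) * comb(16, 1)) / comb(20, 5)
        assert res["p_value"].iloc[0] == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.0320, abs=1e-4)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = dn.fisher_enrichment(universe[:3], universe,
                                   {"s": universe[5:8]})
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_query_equals_universe(self):
        universe = [f"g{i}" for i in range(8)]
        res = dn.fisher_enrichment(universe, universe, {"s": universe[:4]})
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            dn.fisher_enrichment(["x"], ["a", "b"], {"s": ["a"]})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            dn.fisher_enrichment([], [], {"s": ["a"]})


class TestDegreeTables:
    def test_single_edge(self, ensemble_factory):
        scores = np.zeros((2, 1))
        scores[0, 0] = 2.5  # edge t1 -> g1
        ens = ensemble_factory(["t1"], ["g1", "g2"], scores)
        din = dn.degree_table(ens, "gene_in").values
        dout = dn.degree_table(ens, "tf_out").values
        assert din.loc["g1"].iloc[0] == 2.5 and din.loc["g2"].iloc[0] == 0.0
        assert dout.loc["t1"].iloc[0] == 2.5

    def test_two_by_two_arithmetic(self, ensemble_factory):
        # W = [[1,2],[3,4]] -> in (4,6), out (3,7), both total 10
        ens = ensemble_factory(["t1", "t2"], ["g1", "g2"],
                               np.array([[1.0], [2.0], [3.0], [4.0]]))
        din = dn.degree_table(ens, "gene_in").values.iloc[:, 0]
        dout = dn.degree_table(ens, "tf_out").values.iloc[:, 0]
        assert list(din) == [4.0, 6.0]
        assert list(dout) == [3.0, 7.0]
        assert din.sum() == dout.sum() == 10.0

    def test_conservation_every_network(self, small_ensembles):
        ens_f, _, _ = small_ensembles
        din = dn.degree_table(ens_f, "gene_in").values
        dout = dn.degree_table(ens_f, "tf_out").values
        np.testing.assert_allclose(din.sum(axis=0), dout.sum(axis=0), atol=1e-9)
        np.testing.assert_allclose(din.sum(axis=0), ens_f.scores.sum(axis=0),
                                   atol=1e-9)


class TestTfSpecificTable:
    def test_single_network_equals_row(self, toy_ensemble):
        tbl = dn.tf_specific_table(toy_ensemble, "t2")
        np.testing.assert_array_equal(tbl.to_numpy(), toy_ensemble.scores[3:6])

    def test_sums_decompose_in_degree(self, toy_ensemble):
        total = sum(dn.tf_specific_table(toy_ensemble, t) for t in toy_ensemble.tfs)
        din = dn.degree_table(toy_ensemble, "gene_in").values
        np.testing.assert_allclose(total.to_numpy(), din.to_numpy(), atol=1e-12)

    def test_unknown_tf(self, toy_ensemble):
        with pytest.raises(KeyError):
            dn.tf_specific_table(toy_ensemble, "nope")


class TestEdgeClustering:
    def _table_from_matrix(self, M, tfs, genes):
        idx = pd.MultiIndex.from_product([tfs, genes], names=["tf", "gene"])
        t = np.asarray(M).reshape(len(tfs), len(genes)).ravel()
        df = pd.DataFrame({"t_stat": t}, index=idx)
        for col in ("mean_a", "mean_b", "diff", "p_value", "fdr_q"):
            df[col] = 0.0
        return df

    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(4)
        M = np.vstack([base, base, rng.standard_normal(4)]).T  # genes x tf? build tf x gene
        # rows of the clustered matrix are genes: make gene0 == gene1
        tfs = [f"t{i}" for i in range(4)]
        genes = ["g0", "g1", "g2"]
        mat = np.vstack([base, base, rng.standard_normal(4)]).T  # tf x gene
        table = self._table_from_matrix(mat, tfs, genes)
        out = dn.edge_tstat_clustering(table, tfs, genes)
        first_merge = out.row_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_three_row_merge_order_matches_manual_trace(self):
        # hand-computable correlations between gene profiles over 4 TFs
        g0 = np.array([1.0, 2.0, 3.0, 4.0])
        g1 = np.array([1.1, 2.1, 2.9, 4.2])   # r(g0,g1) ~ 0.999
        g2 = np.array([4.0, 1.0, 3.5, 0.5])   # weakly/negatively related
        mat = np.vstack([g0, g1, g2]).T       # tf x gene
        tfs = [f"t{i}" for i in range(4)]
        genes = ["g0", "g1", "g2"]
        table = self._table_from_matrix(mat, tfs, genes)
        out = dn.edge_tstat_clustering(table, tfs, genes)
        # manual complete-linkage on D = 1 - corr
        D = 1.0 - np.corrcoef(np.vstack([g0, g1, g2]))
        assert D[0, 1] < D[0, 2] and D[0, 1] < D[1, 2]
        first = out.row_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(D[0, 1], abs=1e-12)
        # final merge joins g2 at the maximum pairwise distance
        assert out.row_linkage[1][2] == pytest.approx(max(D[0, 2], D[1, 2]),
                                                      abs=1e-12)

    def test_leaf_orders_are_permutations(self, small_ensembles):
        ens_f, ens_m, table = small_ensembles
        out = dn.edge_tstat_clustering(table, ens_f.tfs, ens_f.genes)
        assert sorted(out.row_order) == sorted(ens_f.genes)
        assert sorted(out.col_order) == sorted(ens_f.tfs)

    def test_constant_row_warns(self):
        tfs = ["t0", "t1", "t2"]
        genes = ["g0", "g1"]
        mat = np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 1.5]])  # gene g0 constant
        table = self._table_from_matrix(mat, tfs, genes)
        with pytest.warns(UserWarning, match="constant rows"):
            dn.edge_tstat_clustering(table, tfs, genes)


def test_calibrate_edge_thresholds_targets_band(small_ensembles):
    _, _, table = small_ensembles
    diff_min = dn.diffnet.calibrate_edge_thresholds(table, q_max=0.05)
    sub_a, sub_b = dn.select_sex_specific_edges(table, diff_min=diff_min,
                                                q_max=0.05)
    frac = max(len(sub_a.edges), len(sub_b.edges)) / len(table)
    assert frac <= 0.10  # never grossly above the band
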