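"""Hyperedge construction, incidence assembly, and the Gower comparator."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from hypersurv.graphs import (
    GowerSpec,
    HyperedgeGroup,
    adjacency_edge_group,
    assemble_hypergraph,
    default_gower_spec,
    epsilon_radius_network,
    gower_distance,
    knn_hyperedge_group,
    pae_edge_group,
)


def _sym(rng, n):
    S = rng.random((n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


class TestPaeEdgeGroup:
    def test_three_node_example(self):
        S = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.7], [0.2, 0.7, 1.0]])
        g = pae_edge_group(S, threshold=0.5)
        assert g.members == [(0, 1), (1, 2)]
        np.testing.assert_allclose(g.weights, [0.9, 0.7])

    def test_all_below_threshold_gives_empty_group(self):
        S = np.full((3, 3), 0.1)
        np.fill_diagonal(S, 1.0)
        assert len(pae_edge_group(S, threshold=0.5)) == 0

    def test_matches_brute_force_double_loop(self, rng):
        S = _sym(rng, 10)
        g = pae_edge_group(S, threshold=0.5)
        expected = [
            (i, j) for i in range(10) for j in range(i + 1, 10) if S[i, j] >= 0.5
        ]
        assert g.members == expected
        np.testing.assert_allclose(g.weights, [S[i, j] for i, j in expected])

    def test_threshold_outside_open_interval_errors(self):
        S = np.eye(3)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                pae_edge_group(S, threshold=bad)


class TestKnnHyperedges:
    def test_one_dimensional_example(self):
        g = knn_hyperedge_group(np.array([[0.0], [1.0], [10.0]]), k=1)
        assert g.members == [(0, 1), (1, 0), (2, 1)]

    def test_k_equals_n_minus_one_gives_full_sets(self, rng):
        X = rng.normal(size=(5, 2))
        g = knn_hyperedge_group(X, k=4)
        for m in g.members:
            assert sorted(m) == [0, 1, 2, 3, 4]

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        g1 = knn_hyperedge_group(X, k=3)
        g2 = knn_hyperedge_group(X[perm], k=3)
        # permuted-cohort node j is original node perm[j]
        back_mapped = {frozenset(perm[list(m)].tolist()) for m in g2.members}
        assert back_mapped == {frozenset(m) for m in g1.members}

    def test_k_bounds(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            knn_hyperedge_group(X, k=4)
        with pytest.raises(ValueError):
            knn_hyperedge_group(X, k=0)


class TestAssemble:
    def test_concatenation_order_and_counts(self, rng):
        g1 = HyperedgeGroup("a", [(i, i + 1) for i in range(5)], np.ones(5))
        g2 = HyperedgeGroup("b", [(i, i + 1, i + 2) for i in range(7)], np.ones(7))
        hg = assemble_hypergraph([g1, g2], 9, add_self_edges=False)
        assert hg.n_edges == 12
        assert hg.group_slices["a"] == slice(0, 5)
        assert hg.group_slices["b"] == slice(5, 12)

    def test_pairwise_columns_sum_to_two(self):
        g = HyperedgeGroup("p", [(0, 1), (1, 2), (0, 2)], np.array([0.5, 0.6, 0.7]))
        hg = assemble_hypergraph([g], 3)
        np.testing.assert_array_equal(hg.edge_degrees, [2, 2, 2])

    def test_isolated_node_gets_positive_degree(self):
        g = HyperedgeGroup("p", [(0, 1)], np.array([0.9]))
        S = np.array([[1, 0.9, 0.4], [0.9, 1, 0.2], [0.4, 0.2, 1.0]])
        hg = assemble_hypergraph([g], 3, add_self_edges=True, sim=S)
        assert (hg.node_degrees > 0).all()
        # node 2 was attached to its nearest neighbour under sim (node 0)
        self_col = hg.H[:, hg.group_slices["self"]].toarray().ravel()
        assert self_col[2] == 1 and self_col[0] == 1

    def test_empty_groups_without_augmentation_error(self):
        with pytest.raises(ValueError):
            assemble_hypergraph([], 3, add_self_edges=False)

    def test_two_node_hyperedges_reduce_to_weighted_adjacency(self, rng):
        # H W H^T minus its diagonal equals the weighted graph adjacency
        for _ in range(10):
            n = int(rng.integers(3, 8))
            S = _sym(rng, n)
            g = pae_edge_group(S, threshold=0.4)
            if len(g) == 0:
                continue
            hg = assemble_hypergraph([g], n, add_self_edges=False)
            M = (hg.H.multiply(hg.W) @ hg.H.T).toarray()
            M -= np.diag(np.diag(M))
            adj = np.zeros((n, n))
            for (i, j), w in zip(g.members, g.weights):
                adj[i, j] = adj[j, i] = w
            np.testing.assert_allclose(M, adj, atol=1e-12)

    def test_node_order_equivariance(self, rng):
        n = 6
        S = _sym(rng, n)
        g = pae_edge_group(S, threshold=0.4)
        hg = assemble_hypergraph([g], n, add_self_edges=True, sim=S)
        perm = rng.permutation(n)
        g2 = pae_edge_group(S[np.ix_(perm, perm)], threshold=0.4)
        hg2 = assemble_hypergraph([g2], n, add_self_edges=True, sim=S[np.ix_(perm, perm)])
        # permuting nodes permutes incidence rows identically (columns may reorder)
        cols1 = {frozenset(np.nonzero(hg.H[:, e].toarray().ravel())[0].tolist())
                 for e in range(hg.n_edges)}
        inv = np.argsort(perm)
        cols2 = {frozenset(perm[np.nonzero(hg2.H[:, e].toarray().ravel())[0]].tolist())
                 for e in range(hg2.n_edges)}
        assert cols1 == cols2


class TestGower:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_identical_rows_distance_zero(self):
        df = self._table([{"a": 1.0, "b": "x"}, {"a": 1.0, "b": "x"}])
        spec = GowerSpec({"a": "continuous", "b": "categorical"}, ranges={"a": 2.0})
        assert gower_distance(df, spec)[0, 1] == 0.0

    def test_all_categorical_total_mismatch_is_one(self):
        df = self._table([{"a": "x", "b": "u"}, {"a": "y", "b": "v"}])
        spec = GowerSpec({"a": "categorical", "b": "categorical"})
        assert gower_distance(df, spec)[0, 1] == 1.0

    def test_hand_mixed_example(self):
        # (age 50, male, smoker) vs (age 60, female, smoker), age range 20
        df = self._table(
            [
                {"age": 50.0, "sex": "male", "smoking": "yes"},
                {"age": 60.0, "sex": "female", "smoking": "yes"},
            ]
        )
        spec = GowerSpec(
            {"age": "continuous", "sex": "categorical", "smoking": "categorical"},
            ranges={"age": 20.0},
        )
        assert gower_distance(df, spec)[0, 1] == pytest.approx((0.5 + 1 + 0) / 3)

    def test_missing_values_drop_their_terms(self):
        df = self._table(
            [
                {"age": 50.0, "sex": "male"},
                {"age": np.nan, "sex": "female"},
            ]
        )
        spec = GowerSpec({"age": "continuous", "sex": "categorical"}, ranges={"age": 10.0})
        assert gower_distance(df, spec)[0, 1] == pytest.approx(1.0)  # only sex term left

    def test_pair_with_nothing_observed_errors(self):
        df = self._table([{"age": 1.0}, {"age": np.nan}])
        spec = GowerSpec({"age": "continuous"}, ranges={"age": 1.0})
        with pytest.raises(ValueError, match="pair"):
            gower_distance(df, spec)

    def test_symmetry_bounds_and_rescaling_invariance(self, small_cohort):
        clin = small_cohort[0].clinical
        d = gower_distance(clin, default_gower_spec())
        assert np.abs(d - d.T).max() < 1e-12
        assert (np.diag(d) == 0).all()
        assert d.min() >= 0 and d.max() <= 1
        rescaled = clin.copy()
        rescaled["age"] = 10.0 + 3.0 * rescaled["age"]  # range recomputed from data
        d2 = gower_distance(rescaled, default_gower_spec())
        np.testing.assert_allclose(d, d2, atol=1e-9)

    def test_matches_r_cluster_daisy(self, tmp_path, small_cohort):
        clin = small_cohort[0].clinical.head(12).copy()
        csv = tmp_path / "clin.csv"
        clin.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(cluster))
            x <- read.csv("{csv}", stringsAsFactors = TRUE)
            x$patient_id <- NULL
            x$treatment_line <- as.ordered(x$treatment_line)
            d <- daisy(x, metric = "gower")
            write.csv(as.matrix(d), "{tmp_path / 'd.csv'}")
            """
        )
        (tmp_path / "gower.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "gower.R")], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "d.csv", index_col=0).to_numpy()
        ours = gower_distance(clin, default_gower_spec())
        np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestEpsilonRadius:
    def test_boundary_cases(self):
        d = np.array([[0.0, 0.49], [0.49, 0.0]])
        assert epsilon_radius_network(d, 0.5)[0, 1] == 1
        d[0, 1] = d[1, 0] = 0.51
        assert epsilon_radius_network(d, 0.5)[0, 1] == 0
        d[0, 1] = d[1, 0] = 0.50
        assert epsilon_radius_network(d, 0.5)[0, 1] == 1  # inclusive boundary

    def test_nonpositive_epsilon_errors(self):
        with pytest.raises(ValueError):
            epsilon_radius_network(np.zeros((2, 2)), 0.0)

    def test_adjacency_edge_group_enumerates_upper_triangle(self, rng):
        adj = (rng.random((6, 6)) < 0.4).astype(int)
        adj = np.triu(adj, 1) + np.triu(adj, 1).T
        g = adjacency_edge_group(adj)
        assert g.members == [
            (i, j) for i in range(6) for j in range(i + 1, 6) if adj[i, j]
        ]
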