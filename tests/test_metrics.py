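"""Centrality, centralisation and clique metrics against analytic cases and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agonet.metrics import (
    DegenerateNetworkWarning,
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    freeman_centralisation,
    largest_clique_size,
    network_traits,
    pen_trait_table,
)
from .conftest import path_adjacency, random_adjacency, ring_adjacency, star_adjacency
from .oracles import (
    brute_betweenness,
    brute_clique_number,
    dense_eigenvector,
    nx_clique_number,
    nx_closeness,
    to_nx,
)


class TestDegree:
    def test_star_hub_and_leaves(self):
        scores = degree_centrality(star_adjacency(15), "total").values
        assert scores[0] == 14
        assert np.all(scores[1:] == 1)

    def test_all_attack_one_victim(self):
        # 14 pigs each attack pig 0 once: in-degree 14, out-degree 0
        adj = np.zeros((15, 15), dtype=int)
        adj[1:, 0] = 1
        assert degree_centrality(adj, "in").values[0] == 14
        assert degree_centrality(adj, "out").values[0] == 0
        assert degree_centrality(adj, "out").values[1] == 1

    def test_ring_all_two(self):
        assert np.all(degree_centrality(ring_adjacency(15), "total").values == 2)

    def test_in_degree_rejected_on_undirected(self):
        with pytest.raises(ValueError, match="directed"):
            degree_centrality(ring_adjacency(5), "in")

    def test_total_counts_distinct_partners_both_directions(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = 1
        adj[1, 0] = 1  # mutual pair still one partner each
        adj[0, 2] = 1
        assert list(degree_centrality(adj, "total").values) == [2, 1, 1]


class TestBetweenness:
    def test_short_path_centre(self):
        scores = betweenness_centrality(path_adjacency(3)).values
        assert scores.tolist() == [0.0, 1.0, 0.0]

    def test_path_four_interior(self):
        scores = betweenness_centrality(path_adjacency(4)).values
        assert scores.tolist() == [0.0, 2.0, 2.0, 0.0]

    def test_disconnected_triangles_all_zero(self):
        adj = np.zeros((6, 6), dtype=int)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = 1
        assert np.all(betweenness_centrality(adj).values == 0)

    @pytest.mark.parametrize("directed", [False, True])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_path_enumeration(self, seed, directed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(8, 0.35, rng, directed=directed)
        got = betweenness_centrality(adj, directed=directed).values
        expected = brute_betweenness(adj, directed=directed)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestEigenvector:
    def test_complete_graph_symmetry(self):
        adj = 1 - np.eye(4, dtype=int)
        np.testing.assert_allclose(eigenvector_centrality(adj).values, 1.0)

    def test_star_hub_dominates(self):
        scores = eigenvector_centrality(star_adjacency(15)).values
        assert scores[0] == 1.0
        assert np.allclose(scores[1:], scores[1])
        assert scores[1] < 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_eigendecomposition(self, seed):
        rng = np.random.default_rng(100 + seed)
        adj = random_adjacency(8, 0.3, rng)
        got = eigenvector_centrality(adj).values
        np.testing.assert_allclose(got, dense_eigenvector(adj), atol=1e-8)

    def test_edgeless_is_degenerate(self):
        with pytest.warns(DegenerateNetworkWarning):
            scores = eigenvector_centrality(np.zeros((5, 5), dtype=int)).values
        assert np.all(scores == 0)


class TestCloseness:
    def test_path_three(self):
        scores = closeness_centrality(path_adjacency(3)).values
        np.testing.assert_allclose(scores, [2 / 3, 1.0, 2 / 3])

    def test_complete_graph_all_one(self):
        adj = 1 - np.eye(6, dtype=int)
        np.testing.assert_allclose(closeness_centrality(adj).values, 1.0)

    def test_isolate_scores_zero(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        scores = closeness_centrality(adj).values
        assert scores[2] == 0 and scores[3] == 0


class TestFreemanCentralisation:
    """Star networks attain 1 for degree/betweenness/closeness; rings 0."""

    @pytest.mark.parametrize(
        "factory",
        [
            lambda a: degree_centrality(a, "total"),
            lambda a: betweenness_centrality(a),
            lambda a: closeness_centrality(a),
        ],
        ids=["degree", "betweenness", "closeness"],
    )
    def test_star_attains_one(self, factory):
        assert freeman_centralisation(factory(star_adjacency(15))) == 1.0

    @pytest.mark.parametrize("n", [3, 7, 15])
    @pytest.mark.parametrize(
        "factory",
        [
            lambda a: degree_centrality(a, "total"),
            lambda a: betweenness_centrality(a),
            lambda a: closeness_centrality(a),
            lambda a: eigenvector_centrality(a),
        ],
        ids=["degree", "betweenness", "closeness", "eigenvector"],
    )
    def test_ring_is_zero(self, factory, n):
        assert freeman_centralisation(factory(ring_adjacency(n))) == 0.0

    def test_path_four_hand_computed(self):
        # degrees (1,2,2,1): sum of diffs 2, max (n-1)(n-2)=6 -> 1/3
        assert freeman_centralisation(
            degree_centrality(path_adjacency(4), "total")
        ) == pytest.approx(1 / 3)
        # betweenness (0,2,2,0): sum 4, max (n-1)^2(n-2)/2 = 9 -> 4/9
        assert freeman_centralisation(
            betweenness_centrality(path_adjacency(4))
        ) == pytest.approx(4 / 9)

    def test_directed_in_star(self):
        # all attack pig 0: in-degree scores (14,0,...,0), max (n-1)^2
        adj = np.zeros((15, 15), dtype=int)
        adj[1:, 0] = 1
        assert freeman_centralisation(degree_centrality(adj, "in")) == 1.0

    def test_eigenvector_dyad_attains_one(self):
        adj = np.zeros((15, 15), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        assert freeman_centralisation(eigenvector_centrality(adj)) == pytest.approx(1.0)

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError, match="n=2"):
            freeman_centralisation(np.array([1.0, 0.0]), metric="degree", directed=False)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_on_random_graphs(self, seed):
        rng = np.random.default_rng(2000 + seed)
        adj = random_adjacency(15, rng.uniform(0.05, 0.5), rng)
        if adj.sum() == 0:
            return
        for scores in (
            degree_centrality(adj, "total"),
            betweenness_centrality(adj),
            eigenvector_centrality(adj),
            closeness_centrality(adj),
        ):
            assert 0.0 <= freeman_centralisation(scores) <= 1.0


class TestLargestClique:
    def test_complete_graph(self):
        assert largest_clique_size(1 - np.eye(15, dtype=int)) == 15

    def test_triangle_free_ring(self):
        assert largest_clique_size(ring_adjacency(15)) == 2

    def test_edgeless_is_one(self):
        assert largest_clique_size(np.zeros((15, 15), dtype=int)) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_subset_enumeration(self, seed):
        rng = np.random.default_rng(300 + seed)
        adj = random_adjacency(10, rng.uniform(0.2, 0.7), rng)
        assert largest_clique_size(adj) == brute_clique_number(adj)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_under_edge_addition(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(9, 0.3, rng)
        before = largest_clique_size(adj)
        free = np.argwhere((adj == 0) & ~np.eye(9, dtype=bool))
        if len(free):
            i, j = free[rng.integers(len(free))]
            adj[i, j] = adj[j, i] = 1
        assert largest_clique_size(adj) >= before


class TestOracleEquivalence:
    """Every centrality agrees with networkx on random pen-sized graphs."""

    @pytest.mark.parametrize("seed", range(100))
    def test_all_metrics_match_networkx(self, seed):
        import networkx as nx

        rng = np.random.default_rng(4000 + seed)
        adj = random_adjacency(15, rng.uniform(0.1, 0.5), rng)
        if adj.sum() == 0:
            return
        g = to_nx(adj)
        deg = degree_centrality(adj, "total").values
        np.testing.assert_allclose(deg, [d for _, d in g.degree()], atol=1e-8)
        btw = betweenness_centrality(adj).values
        np.testing.assert_allclose(
            btw,
            list(nx.betweenness_centrality(g, normalized=False).values()),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            closeness_centrality(adj).values, nx_closeness(adj), atol=1e-8
        )
        np.testing.assert_allclose(
            eigenvector_centrality(adj).values, dense_eigenvector(adj), atol=1e-8
        )
        assert largest_clique_size(adj) == nx_clique_number(adj)


class TestNodeLabelInvariance:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_pen_properties_invariant_under_relabelling(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(10, 0.3, rng)
        if adj.sum() == 0:
            return
        perm = rng.permutation(10)
        permuted = adj[np.ix_(perm, perm)]
        for a, b in [(adj, permuted)]:
            assert freeman_centralisation(
                degree_centrality(a, "total")
            ) == pytest.approx(
                freeman_centralisation(degree_centrality(b, "total"))
            )
            assert freeman_centralisation(betweenness_centrality(a)) == pytest.approx(
                freeman_centralisation(betweenness_centrality(b))
            )
            assert largest_clique_size(a) == largest_clique_size(b)


class TestPenTraitTable:
    def test_zero_event_pen_is_degenerate(self):
        from .conftest import toy_events, toy_roster

        table = pen_trait_table(toy_events([]), toy_roster())
        fight = table[table["behaviour"] == "fight"].iloc[0]
        assert fight["degenerate"]
        assert fight["largest_clique_size"] == 1
        assert fight["betweenness_centralisation"] == 0.0

    def test_seven_clique_with_isolates(self):
        from .conftest import toy_events, toy_roster

        roster = toy_roster()
        pigs = roster["pig_id"].tolist()
        rows = [
            (pigs[i], pigs[j], "fight", 10, 0)
            for i in range(7)
            for j in range(i + 1, 7)
        ]
        table = pen_trait_table(toy_events(rows), roster, ("fight",))
        assert table.iloc[0]["largest_clique_size"] == 7

    def test_synthetic_herd_centralisations_in_unit_interval(self, small_herd):
        _, roster, events, _ = small_herd
        table = pen_trait_table(events, roster)
        for col in [c for c in table.columns if c.endswith("centralisation")]:
            vals = table[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all(), col

    def test_directed_columns_only_for_bullying(self, small_herd):
        _, roster, events, _ = small_herd
        table = pen_trait_table(events, roster)
        fight = table[table["behaviour"] == "fight"]
        bully = table[table["behaviour"] == "bully"]
        assert fight["in_degree_centralisation"].isna().all()
        assert bully["in_degree_centralisation"].notna().all()
        assert bully["out_degree_centralisation"].notna().all()
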