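"""Graph metrics against hand counts and brute-force oracles."""

import itertools

import numpy as np
import pytest

import stratnet as sn
from stratnet import WeightedGraph
from tests.conftest import make_random_graph


def path_graph(n):
    return WeightedGraph(
        tuple(f"v{i}" for i in range(n)),
        {(i, i + 1): (1.0, None) for i in range(n - 1)},
    )


def complete_graph(n, w=1.0):
    return WeightedGraph(
        tuple(f"v{i}" for i in range(n)),
        {(i, j): (w, None) for i in range(n) for j in range(i + 1, n)},
    )


def star_graph(leaves=4):
    return WeightedGraph(
        tuple(f"v{i}" for i in range(leaves + 1)),
        {(0, j): (1.0, None) for j in range(1, leaves + 1)},
    )


def cycle_graph(n):
    edges = {(i, i + 1): (1.0, None) for i in range(n - 1)}
    edges[(0, n - 1)] = (1.0, None)
    return WeightedGraph(tuple(f"v{i}" for i in range(n)), edges)


# --- independent oracles ----------------------------------------------------

def floyd_warshall_hops(graph):
    n = graph.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (i, j) in graph.edges:
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def dense_eigvec_oracle(graph):
    a = np.abs(graph.weight_matrix())
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, -1])
    return v / v.max()


def triangle_count_oracle(graph, v):
    nbrs = graph.neighbors(v)
    return sum(
        1
        for a, b in itertools.combinations(nbrs, 2)
        if (min(a, b), max(a, b)) in graph.edges
    )


class TestDensity:
    @pytest.mark.parametrize("m,expected", [(60, 0.441), (68, 0.500)])
    def test_study_edge_counts(self, m, expected):
        full = sorted(complete_graph(17).edges.items())
        g = WeightedGraph(complete_graph(17).nodes, dict(full[:m]))
        assert round(sn.density(g), 3) == expected

    def test_extremes(self):
        assert sn.density(WeightedGraph(("a", "b", "c"))) == 0.0
        assert sn.density(complete_graph(9)) == 1.0

    def test_adding_edge_increases_density(self):
        g = path_graph(5)
        d0 = sn.density(g)
        g2 = WeightedGraph(g.nodes, {**g.edges, (0, 4): (0.5, None)})
        assert sn.density(g2) > d0


class TestShortestPaths:
    def test_path_graph_hand_count(self):
        apl, diam = sn.shortest_path_stats(path_graph(4))
        assert diam == 3
        assert apl == pytest.approx(10 / 6)

    def test_complete_graph(self):
        apl, diam = sn.shortest_path_stats(complete_graph(17))
        assert apl == 1.0 and diam == 1

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            g = make_random_graph(rng)
            d = floyd_warshall_hops(g)
            finite = d[np.isfinite(d) & (d > 0)]
            apl, diam = sn.shortest_path_stats(g)
            assert apl == pytest.approx(finite.mean())
            assert diam == int(finite.max())

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            sn.shortest_path_stats(WeightedGraph(("a", "b")))

    def test_new_edge_never_increases_apl(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            g = make_random_graph(rng, n=8, edge_prob=0.5)
            missing = [
                (i, j)
                for i in range(8)
                for j in range(i + 1, 8)
                if (i, j) not in g.edges
            ]
            if not missing:
                continue
            # compare over pairs reachable in both (unreachable pairs
            # entering the mean can legitimately raise it)
            d0 = floyd_warshall_hops(g)
            g2 = WeightedGraph(g.nodes, {**g.edges, missing[0]: (1.0, None)})
            d1 = floyd_warshall_hops(g2)
            both = np.isfinite(d0)
            assert np.all(d1[both] <= d0[both])


class TestEigenvector:
    def test_star_hub_dominates(self):
        scores = sn.eigenvector_centrality(star_graph(4))
        assert scores[0] == pytest.approx(1.0)
        assert np.allclose(scores[1:], scores[1])
        assert scores[1] < 1.0

    def test_cycle_all_equal(self):
        scores = sn.eigenvector_centrality(cycle_graph(6))
        np.testing.assert_allclose(scores, 1.0, atol=1e-7)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            g = make_random_graph(rng)
            mine = sn.eigenvector_centrality(g)
            oracle = dense_eigvec_oracle(g)
            np.testing.assert_allclose(mine, oracle, atol=1e-6)

    def test_invariant_to_uniform_weight_scaling(self):
        rng = np.random.default_rng(15)
        g = make_random_graph(rng, n=10)
        scaled = WeightedGraph(
            g.nodes, {e: (7.3 * w, p) for e, (w, p) in g.edges.items()}
        )
        np.testing.assert_allclose(
            sn.eigenvector_centrality(g),
            sn.eigenvector_centrality(scaled),
            atol=1e-7,
        )


class TestCloseness:
    def test_path_graph_hand_count(self):
        scores = sn.closeness_centrality(path_graph(3))
        assert scores[1] == pytest.approx(1.0)
        assert scores[0] == pytest.approx(2 / 3)

    def test_isolated_node_zero(self):
        g = WeightedGraph(("a", "b", "c"), {(0, 1): (1.0, None)})
        assert sn.closeness_centrality(g)[2] == 0.0

    def test_matches_bfs_oracle_with_component_correction(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            g = make_random_graph(rng, edge_prob=0.25)
            d = floyd_warshall_hops(g)
            n = g.n_nodes
            expected = np.zeros(n)
            for v in range(n):
                reach = np.isfinite(d[v]) & (d[v] > 0)
                if reach.any():
                    nr = reach.sum()
                    expected[v] = (nr / d[v][reach].sum()) * (nr / (n - 1))
            np.testing.assert_allclose(sn.closeness_centrality(g), expected)


class TestClustering:
    def test_triangle_all_one(self):
        per, avg = sn.clustering_coefficients(complete_graph(3))
        np.testing.assert_array_equal(per, 1.0)
        assert avg == 1.0

    def test_star_all_zero(self):
        per, avg = sn.clustering_coefficients(star_graph(4))
        np.testing.assert_array_equal(per, 0.0)
        assert avg == 0.0

    def test_matches_triple_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            g = make_random_graph(rng)
            per, _ = sn.clustering_coefficients(g)
            for v in range(g.n_nodes):
                k = g.degree(v)
                expected = (
                    2 * triangle_count_oracle(g, v) / (k * (k - 1))
                    if k >= 2
                    else 0.0
                )
                assert per[v] == pytest.approx(expected)


class TestVertexTransitive:
    @pytest.mark.parametrize("graph", [cycle_graph(7), complete_graph(6)])
    def test_all_centralities_equal(self, graph):
        for scores in (
            sn.eigenvector_centrality(graph),
            sn.closeness_centrality(graph),
            sn.clustering_coefficients(graph)[0],
        ):
            np.testing.assert_allclose(scores, scores[0], atol=1e-7)


class TestActivationView:
    def test_star_hub_activates_all(self):
        view = sn.activation_view(star_graph(4), "v0")
        assert len(view.activated) == 4 and not view.deactivated

    def test_isolated_node_activates_none(self):
        g = WeightedGraph(("a", "b", "c"), {(0, 1): (1.0, None)})
        view = sn.activation_view(g, "c")
        assert not view.activated and set(view.deactivated) == {"a", "b"}

    def test_sorted_by_abs_weight_sign_kept(self):
        g = WeightedGraph(
            ("a", "b", "c", "d"),
            {(0, 1): (0.2, None), (0, 2): (-0.9, None), (0, 3): (0.5, None)},
        )
        view = sn.activation_view(g, "a")
        assert [x[0] for x in view.activated] == ["c", "d", "b"]
        assert view.activated[0][1] == -0.9

    def test_partition_sizes(self):
        # a node with 11 of 16 possible links splits the rest 11/5
        edges = {(0, j): (0.3, None) for j in range(1, 12)}
        g = WeightedGraph(tuple(f"v{i}" for i in range(17)), edges)
        view = sn.activation_view(g, "v0")
        assert len(view.activated) == 11 and len(view.deactivated) == 5

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            sn.activation_view(star_graph(3), "nope")
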