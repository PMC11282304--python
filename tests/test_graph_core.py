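"""Graph container, edge-list I/O and topological quantities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ierw.graph_core import (ConnectivityError, ContractError, GraphInputError,
                             WeightedGraph, degree_stats,
                             largest_connected_component, mean_edge_weight,
                             read_edge_list, shortest_path_matrix, write_edge_list)
from ierw.ierw_loop import node2vec_weight_t

from conftest import make_graph


class TestReadEdgeList:
    def test_unweighted_default(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("a b\nb c\nc a\n")
        g = read_edge_list(p)
        assert g.n_nodes == 3 and g.n_edges == 3
        assert g.semantics == "unweighted"
        assert np.all(g.weights == 1.0)

    def test_duplicate_last_wins(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("a b 0.5\nb c 1.0\nc a 1.0\nb a 0.7\n")
        g = read_edge_list(p, semantics="distance")
        assert g.n_edges == 3
        i, j = g.index_of("a"), g.index_of("b")
        mask = (g.edges[:, 0] == min(i, j)) & (g.edges[:, 1] == max(i, j))
        assert g.weights[mask][0] == 0.7

    def test_disconnected_raises(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("a b\nb c\nc a\nx y\ny z\nz x\n")
        with pytest.raises(ConnectivityError):
            read_edge_list(p)

    def test_bad_weight_names_line(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("a b 1.0\nb c -2\n")
        with pytest.raises(GraphInputError, match=":2"):
            read_edge_list(p, semantics="distance")

    def test_self_loop_dropped(self, tmp_path, caplog):
        p = tmp_path / "g.edges"
        p.write_text("a a\na b\nb c\nc a\n")
        with caplog.at_level("WARNING"):
            g = read_edge_list(p)
        assert g.n_edges == 3
        assert any("self-loop" in r.message for r in caplog.records)

    def test_comments_ignored(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("# a comment\na b\nb c\nc a\n")
        assert read_edge_list(p).n_edges == 3

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        edges = [("n%d" % i, "n%d" % j) for i, j in
                 itertools.combinations(range(8), 2) if rng.random() < 0.6]
        g = make_graph(edges, weights=rng.uniform(0.1, 2.0, len(edges)),
                       semantics="distance")
        p = tmp_path / "g.edges"
        write_edge_list(g, p)
        g2 = read_edge_list(p, semantics="distance")
        assert set(g.nodes) == set(g2.nodes)
        w1 = {(g.nodes[u], g.nodes[v]): w for (u, v), w in zip(g.edges, g.weights)}
        w2 = {(g2.nodes[u], g2.nodes[v]): w for (u, v), w in zip(g2.edges, g2.weights)}
        key = lambda d: {tuple(sorted(k)): v for k, v in d.items()}
        k1, k2 = key(w1), key(w2)
        assert k1.keys() == k2.keys()
        for k in k1:
            assert k1[k] == pytest.approx(k2[k], abs=1e-9)


class TestInvariants:
    def test_rejects_self_loop(self):
        with pytest.raises(GraphInputError):
            WeightedGraph(("a", "b", "c"), np.array([[0, 0], [0, 1], [1, 2]]),
                          np.ones(3), "unweighted")

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(GraphInputError):
            WeightedGraph(("a", "b", "c"), np.array([[0, 1], [1, 2]]),
                          np.array([1.0, 0.0]), "distance")

    def test_rejects_tiny_graph(self):
        with pytest.raises(GraphInputError):
            WeightedGraph(("a", "b"), np.array([[0, 1]]), np.ones(1), "unweighted")


class TestLargestComponent:
    def test_connected_identity(self, triangle):
        g = largest_connected_component(triangle.nodes, triangle.edges,
                                        triangle.weights, "unweighted")
        assert set(g.nodes) == set(triangle.nodes)
        assert g.n_edges == triangle.n_edges

    def test_size_order(self):
        nodes = tuple("abcdefgh")
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [0, 4],   # 5-cycle
                          [5, 6], [6, 7], [7, 5]])                  # triangle
        g = largest_connected_component(nodes, edges, np.ones(8), "unweighted")
        assert set(g.nodes) == set("abcde")

    def test_tie_smallest_identifier(self):
        nodes = ("z1", "z2", "z3", "z4", "a1", "a2", "a3", "a4")
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 0],
                          [4, 5], [5, 6], [6, 7], [7, 4]])
        g = largest_connected_component(nodes, edges, np.ones(8), "unweighted")
        assert set(g.nodes) == {"a1", "a2", "a3", "a4"}


class TestDegreeStats:
    def test_regular_graph_gives_node2vec_t_ten(self):
        # 20-regular circulant: mean = mode = 20, so t = 10·20/20 = 10
        n = 30
        edges = [(i, (i + k) % n) for i in range(n) for k in range(1, 11)]
        g = make_graph(sorted({(min(u, v), max(u, v)) for u, v in edges}))
        mean, mode = degree_stats(g)
        assert mean == 20.0 and mode == 20
        assert node2vec_weight_t(g) == pytest.approx(10.0)

    def test_star(self):
        g = make_graph([("c", "a"), ("c", "b"), ("c", "d")])
        mean, mode = degree_stats(g)
        assert mean == pytest.approx(1.5)
        assert mode == 1

    def test_mode_tie_smallest(self):
        # path a-b-c-d plus edge b-d: degrees {1,2,3,2}? adjust to {2,2,3,3}
        g = make_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")])
        mean, mode = degree_stats(g)  # degrees 3,2,3,2
        assert mode == 2

    def test_mean_exact(self, two_cliques_bridge):
        mean, _ = degree_stats(two_cliques_bridge)
        assert mean == 2 * two_cliques_bridge.n_edges / two_cliques_bridge.n_nodes


class TestShortestPaths:
    def test_hop_counts(self):
        g = make_graph([("a", "b"), ("b", "c"), ("a", "d"), ("d", "c")])
        m = shortest_path_matrix(g)
        i, k = g.index_of("a"), g.index_of("c")
        assert m.spl[i, k] == 2
        assert m.spl_max == 2

    def test_detour_beats_heavy_edge(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "a")],
                       weights=[1.0, 1.0, 3.0], semantics="distance")
        m = shortest_path_matrix(g)
        i, k = g.index_of("c"), g.index_of("a")
        assert m.spl[i, k] == pytest.approx(2.0)

    def test_against_path_enumeration(self):
        rng = np.random.default_rng(3)
        nodes = list("abcde")
        edges = [(u, v) for u, v in itertools.combinations(nodes, 2)
                 if rng.random() < 0.7]
        w = rng.uniform(0.2, 2.0, len(edges))
        g = make_graph(edges, weights=w, semantics="distance")
        lengths = {tuple(sorted((u, v))): ww for (u, v), ww in zip(edges, w)}

        def brute(u, v):
            best = np.inf
            for k in range(len(nodes)):
                for mid in itertools.permutations([x for x in g.nodes if x not in (u, v)], k):
                    path = (u, *mid, v)
                    tot = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        kk = tuple(sorted((a, b)))
                        if kk not in lengths:
                            ok = False
                            break
                        tot += lengths[kk]
                    if ok:
                        best = min(best, tot)
            return best

        m = shortest_path_matrix(g)
        for u, v in itertools.combinations(g.nodes, 2):
            assert m.spl[g.index_of(u), g.index_of(v)] == pytest.approx(brute(u, v), abs=1e-9)

    def test_proximity_rejected(self, triangle):
        g = triangle.with_weights(np.ones(3), "proximity")
        with pytest.raises(ContractError):
            shortest_path_matrix(g)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            edges = [(i, j) for i, j in itertools.combinations(range(8), 2)
                     if rng.random() < 0.45]
            try:
                g = make_graph(edges, weights=rng.uniform(0.1, 3.0, len(edges)),
                               semantics="distance", nodes=list(range(8)))
                break
            except Exception:
                continue
        spl = shortest_path_matrix(g).spl
        for i, j, k in itertools.permutations(range(8), 3):
            assert spl[i, j] <= spl[i, k] + spl[k, j] + 1e-9


class TestMeanWeight:
    def test_values(self, triangle):
        assert mean_edge_weight(triangle) == 1.0
        g = make_graph([("a", "b"), ("b", "c"), ("c", "a")],
                       weights=[0.2, 0.4, 0.3], semantics="distance")
        assert mean_edge_weight(g) == pytest.approx(0.3)

    def test_random_against_independent_sum(self):
        rng = np.random.default_rng(11)
        edges = [(0, i) for i in range(1, 51)] + [(1, i) for i in range(2, 51)]
        w = rng.uniform(0.01, 5.0, len(edges))
        g = make_graph(edges, weights=w, semantics="distance",
                       nodes=list(range(51)))
        total = 0.0
        for x in w:
            total += x
        assert mean_edge_weight(g) == pytest.approx(total / len(w), abs=1e-12)
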