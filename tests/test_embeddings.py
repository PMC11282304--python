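"""Embedding backends: oracles, determinism, angular structure."""

import numpy as np
import pytest
import scipy.linalg

from ierw.embeddings import (BackendConfig, Embedding, cosine_of_angle,
                             default_exponential_t, embed_iso, embed_le,
                             embed_node2vec, embed_trexpic, pairwise_cosines)
from ierw.graph_core import ContractError, shortest_path_matrix

from conftest import make_graph


def emb_from(positions):
    n = len(positions)
    return Embedding(tuple(str(i) for i in range(n)), np.asarray(positions, float),
                     "euclidean", "test")


class TestCosine:
    def test_identical_direction(self):
        e = emb_from([[2, 0], [4, 0]])
        assert cosine_of_angle(e, 0, 1) == pytest.approx(1.0)

    def test_opposite(self):
        e = emb_from([[1, 0], [-3, 0]])
        assert cosine_of_angle(e, 0, 1) == pytest.approx(-1.0)

    def test_45_degrees(self):
        e = emb_from([[1, 0], [1, 1]])
        assert cosine_of_angle(e, 0, 1) == pytest.approx(0.7071068, abs=1e-6)

    def test_zero_norm_rejected(self):
        e = emb_from([[0, 0], [1, 1]])
        with pytest.raises(ContractError):
            cosine_of_angle(e, 0, 1)


class TestLaplacianEigenmaps:
    def test_scale_invariance(self, two_cliques_bridge):
        g = two_cliques_bridge
        w = np.linspace(0.5, 1.5, g.n_edges)
        g1 = g.with_weights(w, "distance")
        g2 = g.with_weights(7.3 * w, "distance")
        e1, e2 = embed_le(g1, 2), embed_le(g2, 2)
        assert np.allclose(e1.positions, e2.positions, atol=1e-9)

    def test_dense_generalized_oracle(self):
        """Positions span the same subspace as a direct dense solve of
        L f = λ D f on the exponential proximity weights."""
        rng = np.random.default_rng(2)
        n = 10
        while True:
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.5]
            try:
                g = make_graph(edges, weights=rng.uniform(0.3, 2.0, len(edges)),
                               semantics="distance", nodes=list(range(n)))
                break
            except Exception:
                continue
        d = 3
        emb = embed_le(g, d)
        # oracle: dense generalized eigenproblem, independent construction
        t = g.weights.mean() ** 2
        a = np.zeros((n, n))
        for (u, v), w in zip(g.edges, g.weights):
            a[u, v] = a[v, u] = np.exp(-w**2 / t)
        deg = a.sum(axis=1)
        lap = np.diag(deg) - a
        lam, f = scipy.linalg.eigh(lap, np.diag(deg))
        oracle = f[:, 1:d + 1]  # skip the zero mode
        angles = scipy.linalg.subspace_angles(emb.positions, oracle)
        assert np.max(angles) < 1e-6

    def test_mirror_cliques_sign_split(self, two_cliques_bridge):
        emb = embed_le(two_cliques_bridge, 2)
        first = emb.positions[:, 0]
        side_a, side_b = first[:5], first[5:]
        assert np.all(np.sign(side_a) == np.sign(side_a[0]))
        assert np.all(np.sign(side_b) == -np.sign(side_a[0]))

    def test_deterministic(self, small_pp):
        g, _ = small_pp
        e1, e2 = embed_le(g, 2), embed_le(g, 2)
        assert np.array_equal(e1.positions, e2.positions)


class TestTrexpic:
    def test_default_t_formula(self):
        # direct evaluation of sqrt(ln(1/0.9999)·ln(1/0.1))·SPL_max at SPL_max=5
        assert default_exponential_t(5.0) == pytest.approx(0.07587325, abs=1e-7)
        assert default_exponential_t(5.0) == pytest.approx(
            np.sqrt(np.log(1 / 0.9999) * np.log(10)) * 5)

    def test_lorentz_diagonal_is_one(self, two_cliques_bridge):
        # X_ii = 0 => cosh(0) = 1
        spl = shortest_path_matrix(two_cliques_bridge)
        t = default_exponential_t(spl.spl_max)
        with np.errstate(divide="ignore"):
            x = np.exp(-t / spl.spl)
        np.fill_diagonal(x, 0.0)
        lorentz = np.cosh(x)
        assert np.allclose(np.diag(lorentz), 1.0)
        assert np.all(lorentz >= 1.0)

    def test_cosine_symmetry_and_geometry(self, small_pp):
        g, _ = small_pp
        emb = embed_trexpic(g, 3)
        assert emb.geometry == "hyperbolic_native"
        assert emb.positions.shape == (g.n_nodes, 3)
        c = pairwise_cosines(emb)
        assert np.allclose(c, c.T)
        assert "radial" in emb.diagnostics
        assert np.all(emb.diagnostics["radial"] >= 0)

    def test_deterministic(self, small_pp):
        g, _ = small_pp
        assert np.array_equal(embed_trexpic(g, 3).positions,
                              embed_trexpic(g, 3).positions)


class TestIsomap:
    def test_raw_variant_reproduces_line_metric(self):
        g = make_graph([("a", "b"), ("b", "c")])
        emb = embed_iso(g, 2, exponentialized=False)
        p = emb.positions
        d = {(i, j): np.linalg.norm(p[i] - p[j]) for i in range(3) for j in range(3)}
        ia, ib, ic = (g.index_of(x) for x in "abc")
        assert d[ia, ib] == pytest.approx(1.0, abs=1e-8)
        assert d[ib, ic] == pytest.approx(1.0, abs=1e-8)
        assert d[ia, ic] == pytest.approx(2.0, abs=1e-8)

    def test_centroid_at_origin(self, small_pp):
        g, _ = small_pp
        emb = embed_iso(g, 2, exponentialized=False)
        assert np.allclose(emb.positions.mean(axis=0), 0.0, atol=1e-9)

    def test_exponentialized_uses_trexpic_t(self, two_cliques_bridge):
        spl = shortest_path_matrix(two_cliques_bridge)
        emb = embed_iso(two_cliques_bridge, 2)
        assert emb.diagnostics["t"] == pytest.approx(default_exponential_t(spl.spl_max))


@pytest.fixture(scope="module")
def cliques_graph():
    edges = []
    for base in (0, 20):
        for i in range(20):
            for j in range(i + 1, 20):
                edges.append((base + i, base + j))
    edges.append((0, 20))
    return make_graph(edges, nodes=list(range(40)))


class TestNode2vec:
    def test_output_dimension_default(self, cliques_graph):
        emb = embed_node2vec(cliques_graph, cfg=BackendConfig(
            seed=0, walks_per_node=10, epochs=1))
        assert emb.positions.shape == (40, 64)

    def test_clique_cosine_separation(self, cliques_graph):
        """Intra-clique angles beat inter-clique angles in every seed."""
        for seed in range(3):
            emb = embed_node2vec(cliques_graph, cfg=BackendConfig(seed=seed))
            c = pairwise_cosines(emb)
            block = np.array([0] * 20 + [1] * 20)
            same = block[:, None] == block[None, :]
            off = ~np.eye(40, dtype=bool)
            assert c[same & off].mean() > c[~same].mean()

    def test_weak_bridges_widen_margin(self):
        """Down-weighting the inter-clique links (as IERW's exponential rule
        does) widens the intra/inter cosine margin."""
        edges = []
        for base in (0, 10):
            for i in range(10):
                for j in range(i + 1, 10):
                    edges.append((base + i, base + j))
        bridges = [(i, 10 + i) for i in range(5)]
        g0 = make_graph(edges + bridges, nodes=list(range(20)))
        block = np.array([0] * 10 + [1] * 10)
        same = block[:, None] == block[None, :]
        off = ~np.eye(20, dtype=bool)

        def margin(bridge_w, seed):
            w = np.ones(g0.n_edges)
            w[-len(bridges):] = bridge_w
            g = g0.with_weights(w, "proximity")
            emb = embed_node2vec(g, cfg=BackendConfig(seed=seed))
            c = pairwise_cosines(emb)
            return c[same & off].mean() - c[~same].mean()

        seeds = range(3)
        strong = np.mean([margin(1.0, s) for s in seeds])
        weak = np.mean([margin(0.01, s) for s in seeds])
        assert weak > strong

    def test_deterministic_under_seed(self, cliques_graph):
        cfg = BackendConfig(seed=4, walks_per_node=10, epochs=1)
        e1 = embed_node2vec(cliques_graph, cfg=cfg)
        e2 = embed_node2vec(cliques_graph, cfg=cfg)
        assert np.array_equal(e1.positions, e2.positions)

    def test_distance_weights_rejected(self, cliques_graph):
        g = cliques_graph.with_weights(np.ones(cliques_graph.n_edges), "distance")
        with pytest.raises(ContractError):
            embed_node2vec(g)


class TestAllBackendsSeparate:
    def test_pp_intra_beats_inter(self, small_pp):
        """First embedding already separates easy planted communities."""
        g, truth = small_pp
        lab = truth.as_indices(g.nodes)
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(g.n_nodes, dtype=bool)
        embs = [embed_le(g, 2), embed_trexpic(g, 2), embed_iso(g, 2),
                embed_iso(g, 2, exponentialized=False),
                embed_node2vec(g, cfg=BackendConfig(seed=0, walks_per_node=20, epochs=2))]
        for emb in embs:
            c = pairwise_cosines(emb)
            assert c[same & off].mean() > c[~same].mean(), emb.backend
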