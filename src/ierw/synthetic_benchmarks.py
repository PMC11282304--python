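"""Synthetic benchmark graphs with planted community structure.

Three generators are provided, each returning a ``(WeightedGraph,
Partition)`` pair and fully reproducible under a fixed seed:

* :func:`generate_pp` — the planted-partition model: ``C = N/m`` equal
  blocks of ``m`` nodes, one intra-block link probability ``p_in`` and one
  inter-block probability ``p_out`` derived from the target mean degree κ̄
  and the mixing parameter μ (the expected fraction of a node's neighbours
  outside its own block).
* :func:`generate_sbm` — the general stochastic block model with an
  arbitrary symmetric block matrix ``M`` of link probabilities.
* :func:`generate_lfr` — an LFR-style benchmark with power-law degrees
  (tail exponent γ, cut at κ_max) and power-law community sizes (exponent
  β, bounded in [m_min, m_max]), where each node spends a fraction 1−μ of
  its stubs inside its community.  Stubs are matched configuration-model
  style within and between communities, followed by rewiring passes that
  remove self-loops and multi-edges.

All generators resample with a shifted seed (up to ``MAX_RESAMPLE`` times)
when a realization comes out disconnected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .graph_core import Partition, WeightedGraph

logger = logging.getLogger(__name__)

MAX_RESAMPLE = 100
_SEED_STRIDE = 7919  # prime stride for resampling offsets


class GenerationError(RuntimeError):
    """Generator could not produce a valid (connected) realization."""


class ParameterError(ValueError):
    """Inconsistent generator parameters."""


@dataclass(frozen=True)
class PPParams:
    N: int = 1000
    m: int = 50
    mean_degree: float = 20.0
    mu: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.N % self.m != 0:
            raise ParameterError("N must be divisible by the community size m")
        if self.N // self.m < 2:
            raise ParameterError("need at least 2 communities")
        if not 0.0 <= self.mu <= 1.0:
            raise ParameterError("mu must lie in [0, 1]")

    @property
    def C(self) -> int:
        return self.N // self.m


@dataclass(frozen=True)
class LFRParams:
    N: int = 1000
    mean_degree: float = 20.0
    max_degree: int = 50
    degree_exponent: float = 2.0
    m_min: int = 10
    m_max: int = 100
    size_exponent: float = 3.0
    mu: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.m_min <= self.m_max <= self.N):
            raise ParameterError("need 2 <= m_min <= m_max <= N")
        if self.degree_exponent <= 1 or self.size_exponent <= 1:
            raise ParameterError("power-law exponents must exceed 1")
        if self.max_degree > self.N - 1:
            raise ParameterError("max_degree cannot exceed N - 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ParameterError("mu must lie in [0, 1]")


@dataclass(frozen=True)
class SBMParams:
    block_sizes: tuple
    M: tuple  # symmetric matrix of link probabilities, row-major nested
    seed: int = 0

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        sizes = np.asarray(self.block_sizes, dtype=int)
        if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] != len(sizes):
            raise ParameterError("M must be square and match block_sizes")
        if not np.allclose(M, M.T):
            raise ParameterError("M must be symmetric")
        if np.any(M < 0) or np.any(M > 1):
            raise ParameterError("M entries must be probabilities")
        if np.any(sizes <= 0):
            raise ParameterError("block sizes must be positive")


# ---------------------------------------------------------------------------
# Planted partition
# ---------------------------------------------------------------------------

def pp_probabilities(params: PPParams) -> tuple[float, float]:
    """Link probabilities from (κ̄, μ).

    κ̄_out = μ·κ̄ neighbours outside the block and κ̄_in = κ̄ − κ̄_out inside,
    so p_out = κ̄_out / ((C−1)·m) and p_in = κ̄_in / (m−1) (self-loops are
    excluded, hence the m−1).
    """
    kbar_out = params.mu * params.mean_degree
    kbar_in = params.mean_degree - kbar_out
    p_out = kbar_out / ((params.C - 1) * params.m)
    p_in = kbar_in / (params.m - 1)
    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise ParameterError(
            f"derived probabilities out of range: p_in={p_in:.4g}, p_out={p_out:.4g}"
        )
    return p_in, p_out


def _finish(g: nx.Graph, labels: dict, what: str) -> tuple[WeightedGraph, Partition]:
    wg = WeightedGraph.from_networkx(g, semantics="unweighted")
    return wg, Partition({str(k): str(v) for k, v in labels.items()})


def generate_pp(params: PPParams) -> tuple[WeightedGraph, Partition]:
    p_in, p_out = pp_probabilities(params)
    for attempt in range(MAX_RESAMPLE):
        seed = params.seed + _SEED_STRIDE * attempt
        g = nx.planted_partition_graph(params.C, params.m, p_in, p_out, seed=seed)
        g = nx.Graph(g)
        if nx.is_connected(g):
            labels = {v: v // params.m for v in g.nodes()}
            return _finish(g, labels, "pp")
    raise GenerationError(
        f"planted-partition resampling exhausted after {MAX_RESAMPLE} attempts"
    )


def generate_sbm(params: SBMParams) -> tuple[WeightedGraph, Partition]:
    sizes = [int(s) for s in params.block_sizes]
    M = np.asarray(params.M, dtype=float).tolist()
    for attempt in range(MAX_RESAMPLE):
        seed = params.seed + _SEED_STRIDE * attempt
        g = nx.stochastic_block_model(sizes, M, seed=seed)
        g = nx.Graph(g)
        if nx.is_connected(g):
            bounds = np.cumsum([0] + sizes)
            labels = {v: int(np.searchsorted(bounds, v, side="right") - 1) for v in g.nodes()}
            return _finish(g, labels, "sbm")
    raise GenerationError(f"SBM resampling exhausted after {MAX_RESAMPLE} attempts")


# ---------------------------------------------------------------------------
# LFR benchmark
# ---------------------------------------------------------------------------

def _powerlaw_mean(a: float, b: float, gamma: float) -> float:
    """Mean of the continuous power law p(x) ∝ x^-gamma on [a, b]."""
    if abs(gamma - 2.0) < 1e-12:
        return a * b * np.log(b / a) / (b - a)
    g1, g2 = 1.0 - gamma, 2.0 - gamma
    return (g2 and (b**g2 - a**g2) / g2) / ((b**g1 - a**g1) / g1)


def _powerlaw_sample(rng, a: float, b: float, gamma: float, size: int) -> np.ndarray:
    u = rng.random(size)
    g1 = 1.0 - gamma
    return (a**g1 + u * (b**g1 - a**g1)) ** (1.0 / g1)


def _round_half_up(x):
    return np.floor(np.asarray(x) + 0.5).astype(np.int64)


def _draw_degrees(rng, p: LFRParams, max_tries: int = 500) -> np.ndarray:
    """Power-law degree sequence whose mean hits κ̄ within 2%."""
    b = float(p.max_degree)
    lo, hi = 1.0, b - 1e-9
    if not (_powerlaw_mean(lo, b, p.degree_exponent) <= p.mean_degree <= _powerlaw_mean(hi, b, p.degree_exponent)):
        raise ParameterError("mean_degree unreachable with this max_degree/exponent")
    a = brentq(lambda x: _powerlaw_mean(x, b, p.degree_exponent) - p.mean_degree, lo, hi)
    for _ in range(max_tries):
        degs = _round_half_up(_powerlaw_sample(rng, a, b, p.degree_exponent, p.N))
        degs = np.clip(degs, 1, p.max_degree)
        if abs(degs.mean() - p.mean_degree) <= 0.02 * p.mean_degree:
            if degs.sum() % 2 == 1:  # even stub total
                i = rng.integers(p.N)
                degs[i] += 1 if degs[i] < p.max_degree else -1
            return degs
    raise GenerationError("could not match the target mean degree within 2%")


def _draw_sizes(rng, p: LFRParams, max_tries: int = 500) -> np.ndarray:
    """Power-law community sizes adjusted to sum exactly to N."""
    for _ in range(max_tries):
        sizes: list[int] = []
        while sum(sizes) < p.N:
            s = int(_round_half_up(_powerlaw_sample(rng, p.m_min, p.m_max, p.size_exponent, 1))[0])
            sizes.append(int(np.clip(s, p.m_min, p.m_max)))
        excess = sum(sizes) - p.N
        order = rng.permutation(len(sizes))
        for i in order:
            if excess == 0:
                break
            cut = min(excess, sizes[i] - p.m_min)
            sizes[i] -= cut
            excess -= cut
        if excess == 0:
            return np.array(sizes, dtype=np.int64)
    raise GenerationError("could not fit community sizes to N")


def _assign_communities(rng, k_int: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Assign nodes to communities so that k_int fits within size − 1.

    Nodes are placed in decreasing order of internal degree (random tie
    break), each choosing uniformly among the communities that can still
    host it.  A node that fits nowhere with room left goes to the roomiest
    large community and has its internal degree capped downstream.
    """
    n = len(k_int)
    order = np.argsort(-(k_int + rng.random(n)))
    room = sizes.copy()
    comm_of = np.full(n, -1, dtype=np.int64)
    for v in order:
        ok = np.flatnonzero((sizes - 1 >= k_int[v]) & (room > 0))
        if len(ok) == 0:
            ok = np.flatnonzero(room > 0)
        c = int(rng.choice(ok))
        comm_of[v] = c
        room[c] -= 1
    return comm_of


def _intra_edges(rng, nodes_c: np.ndarray, kc: np.ndarray) -> list[tuple[int, int]]:
    """Simple graph on one community realizing the internal degree sequence.

    Havel–Hakimi guarantees a simple realization of any graphical sequence;
    seeded double edge swaps then randomize it while preserving degrees.
    Non-graphical sequences are nudged by moving single stubs from the
    largest internal degrees to the external pool (rare at benchmark scale).
    """
    import networkx as nx

    kc = kc.copy()
    for _ in range(len(kc) + 1):
        if nx.is_graphical(kc.tolist()):
            break
        i = int(np.argmax(kc))
        if kc[i] == 0:
            return []
        kc[i] -= 1
        if kc.sum() % 2 == 1:
            j = int(np.argmax(np.where(np.arange(len(kc)) == i, -1, kc)))
            kc[j] -= 1 if kc[j] > 0 else 0
    if kc.sum() == 0:
        return []
    g = nx.havel_hakimi_graph(kc.tolist())
    nswap = g.number_of_edges()
    if nswap > 1:
        try:
            nx.double_edge_swap(g, nswap=nswap, max_tries=20 * nswap,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXException:
            pass  # near-complete community: few or no swaps possible
    return [(int(min(nodes_c[a], nodes_c[b])), int(max(nodes_c[a], nodes_c[b])))
            for a, b in g.edges()]


def _inter_edges(rng, stubs: np.ndarray, comm_of: np.ndarray,
                 forbidden: set, passes: int = 80) -> list[tuple[int, int]]:
    """Match external stubs across communities.

    Stubs are paired uniformly; pairs that are self-loops, duplicates,
    intra-community, or clash with an existing intra edge are broken up
    together with an equal number of valid pairs and re-paired, repeatedly.
    Irreparable leftovers (a handful at most) are dropped.
    """
    pairs = rng.permutation(stubs).reshape(-1, 2)
    n_pairs = len(pairs)
    for _ in range(passes):
        u, v = pairs[:, 0], pairs[:, 1]
        lo, hi = np.minimum(u, v), np.maximum(u, v)
        keys = lo * (comm_of.size + 1) + hi
        bad = (u == v) | (comm_of[u] == comm_of[v])
        # duplicates: keep the first occurrence of each key
        order = np.argsort(keys, kind="stable")
        dup = np.zeros(n_pairs, dtype=bool)
        sk = keys[order]
        dup[order[1:]] = sk[1:] == sk[:-1]
        bad |= dup
        if forbidden:
            bad |= np.fromiter(((l, h) in forbidden for l, h in zip(lo, hi)),
                               dtype=bool, count=n_pairs)
        idx_bad = np.flatnonzero(bad)
        if len(idx_bad) == 0:
            return list(zip(lo.tolist(), hi.tolist()))
        idx_good = np.flatnonzero(~bad)
        take = min(len(idx_good), max(len(idx_bad), 8))
        mix = np.concatenate([idx_bad, rng.choice(idx_good, size=take, replace=False)
                              if take else np.empty(0, dtype=np.int64)])
        pool = pairs[mix].ravel()
        pool = rng.permutation(pool)
        pairs[mix] = pool.reshape(-1, 2)
    # drop whatever could not be repaired
    u, v = pairs[:, 0], pairs[:, 1]
    lo, hi = np.minimum(u, v), np.maximum(u, v)
    edges, seen, dropped = [], set(), 0
    for l, h in zip(lo.tolist(), hi.tolist()):
        if l == h or comm_of[l] == comm_of[h] or (l, h) in seen or (l, h) in forbidden:
            dropped += 1
            continue
        seen.add((l, h))
        edges.append((l, h))
    logger.debug("inter-community matching dropped %d irreparable pairs", dropped)
    return edges


def generate_lfr(params: LFRParams) -> tuple[WeightedGraph, Partition]:
    for attempt in range(MAX_RESAMPLE):
        rng = np.random.default_rng(params.seed + _SEED_STRIDE * attempt)
        try:
            degs = _draw_degrees(rng, params)
            sizes = _draw_sizes(rng, params)
            k_int = _round_half_up((1.0 - params.mu) * degs)
            comm_of = _assign_communities(rng, k_int, sizes)
            k_int = np.minimum(k_int, sizes[comm_of] - 1)  # cap at size − 1
            k_int = np.minimum(k_int, degs)
            edges: list[tuple[int, int]] = []
            # intra-community configuration model
            for c in range(len(sizes)):
                nodes_c = np.flatnonzero(comm_of == c)
                kc = k_int[nodes_c].copy()
                if kc.sum() % 2 == 1:
                    # parity: move one stub between internal and external
                    room = np.flatnonzero((kc < sizes[c] - 1) & (kc < degs[nodes_c]))
                    if len(room):
                        kc[rng.choice(room)] += 1
                    else:
                        kc[rng.choice(np.flatnonzero(kc > 0))] -= 1
                k_int[nodes_c] = kc
                if kc.sum():
                    comm_edges = _intra_edges(rng, nodes_c, kc)
                    # record the realized internal degrees (graphicality
                    # nudges may have shifted a stub or two to the pool)
                    realized = np.zeros(len(nodes_c), dtype=np.int64)
                    pos = {int(v): i for i, v in enumerate(nodes_c)}
                    for a, b in comm_edges:
                        realized[pos[a]] += 1
                        realized[pos[b]] += 1
                    k_int[nodes_c] = realized
                    edges.extend(comm_edges)
            # inter-community configuration model
            k_ext = degs - k_int
            if k_ext.sum() % 2 == 1:
                cand = np.flatnonzero(k_ext > 0)
                k_ext[rng.choice(cand)] -= 1
            intra_set = {(u, v) for u, v in edges}
            stubs = np.repeat(np.arange(params.N), k_ext)
            if len(stubs):
                edges.extend(_inter_edges(rng, stubs, comm_of, intra_set))
            if not edges:
                raise GenerationError("no edges produced")
            g = WeightedGraph(
                tuple(str(i) for i in range(params.N)),
                np.array(edges, dtype=np.int64),
                np.ones(len(edges)),
                "unweighted",
            )
            part = Partition({str(i): str(int(comm_of[i])) for i in range(params.N)})
            return g, part
        except (GenerationError, ValueError) as exc:
            logger.debug("LFR attempt %d failed: %s", attempt, exc)
            continue
    raise GenerationError(f"LFR resampling exhausted after {MAX_RESAMPLE} attempts")


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def empirical_mixing(graph: WeightedGraph, partition: Partition) -> float:
    """Mean over nodes of the fraction of neighbours in other communities."""
    lab = partition.as_indices(graph.nodes)
    degs = graph.degrees()
    if np.any(degs == 0):
        raise ValueError("empirical mixing undefined for isolated nodes")
    cross = lab[graph.edges[:, 0]] != lab[graph.edges[:, 1]]
    inter = np.zeros(graph.n_nodes)
    np.add.at(inter, graph.edges[:, 0], cross)
    np.add.at(inter, graph.edges[:, 1], cross)
    return float((inter / degs).mean())
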