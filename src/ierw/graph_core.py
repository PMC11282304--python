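"""Graph data model, edge-list I/O and basic topological quantities.

The central container is :class:`WeightedGraph`: a simple, connected,
undirected graph whose edge weights are strictly positive and carry a
*semantics* tag saying how they should be read —

``distance``
    larger weight = nodes farther apart (input for Laplacian Eigenmaps,
    TREXPIC and Isomap),
``proximity``
    larger weight = stronger connection (input for node2vec and for the
    classic community detectors),
``unweighted``
    all weights exactly 1.

Nodes are opaque strings; the internal integer index of a node is its
position in ``graph.nodes`` (order of first appearance in the input).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

logger = logging.getLogger(__name__)

#: Floor applied to distance-like edge lengths before shortest-path
#: computations: angularly coincident nodes produce weights of exactly 0,
#: which would break the exp(-t/SPL) transforms downstream.
EDGE_LENGTH_FLOOR = 1e-10

SEMANTICS = ("distance", "proximity", "unweighted")


class GraphInputError(ValueError):
    """Malformed edge list or membership file."""


class ConnectivityError(ValueError):
    """The graph (or a requested subgraph) is not connected."""


class ContractError(ValueError):
    """An operation was called on a graph with the wrong weight semantics."""


@dataclass(eq=False)
class WeightedGraph:
    """Simple connected undirected graph with positive tagged weights.

    Parameters
    ----------
    nodes
        Node identifiers in index order.
    edges
        ``(E, 2)`` integer array of node-index pairs with ``u < v``.
    weights
        ``(E,)`` array of strictly positive edge weights.
    semantics
        One of ``"distance"``, ``"proximity"``, ``"unweighted"``.
    """

    nodes: tuple[str, ...]
    edges: np.ndarray
    weights: np.ndarray
    semantics: str
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.nodes = tuple(str(n) for n in self.nodes)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if self.validate:
            self._check()

    # -- invariants -------------------------------------------------------
    def _check(self) -> None:
        n, e = len(self.nodes), self.edges.shape[0]
        if n < 3:
            raise GraphInputError(f"graph needs at least 3 nodes, got {n}")
        if len(set(self.nodes)) != n:
            raise GraphInputError("duplicate node identifiers")
        if self.weights.shape[0] != e:
            raise GraphInputError("edge/weight length mismatch")
        if e and (self.edges.min() < 0 or self.edges.max() >= n):
            raise GraphInputError("edge index out of range")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise GraphInputError("self-loop in edge array")
        # canonical orientation u < v, detect parallels
        lo = self.edges.min(axis=1)
        hi = self.edges.max(axis=1)
        self.edges = np.column_stack([lo, hi])
        keys = lo * n + hi
        if len(np.unique(keys)) != e:
            raise GraphInputError("parallel edges in edge array")
        if self.semantics not in SEMANTICS:
            raise GraphInputError(f"unknown semantics {self.semantics!r}")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise GraphInputError("weights must be finite and > 0")
        if self.semantics == "unweighted" and not np.all(self.weights == 1.0):
            raise GraphInputError("unweighted graphs must have unit weights")
        ncomp, _ = connected_components(self.adjacency(), directed=False)
        if ncomp != 1:
            raise ConnectivityError(f"graph has {ncomp} connected components")

    # -- basic quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def index_of(self, node: str) -> int:
        try:
            return self._index[node]
        except AttributeError:
            self._index = {v: i for i, v in enumerate(self.nodes)}
            return self._index[node]

    def adjacency(self, weights: np.ndarray | None = None) -> sp.csr_matrix:
        """Symmetric sparse adjacency matrix (CSR)."""
        w = self.weights if weights is None else weights
        n = self.n_nodes
        u, v = self.edges[:, 0], self.edges[:, 1]
        a = sp.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(n, n),
        )
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        """Topological (unweighted) degree of every node."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(d, self.edges[:, 0], 1)
        np.add.at(d, self.edges[:, 1], 1)
        return d

    def with_weights(self, weights: np.ndarray, semantics: str) -> "WeightedGraph":
        """Same topology, new weights (used by the reweighting step)."""
        return WeightedGraph(self.nodes, self.edges.copy(), weights, semantics)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in zip(self.edges, self.weights):
            g.add_edge(self.nodes[u], self.nodes[v], weight=float(w))
        return g

    @classmethod
    def from_networkx(cls, g, semantics: str = "unweighted") -> "WeightedGraph":
        nodes = tuple(str(v) for v in g.nodes())
        idx = {v: i for i, v in enumerate(g.nodes())}
        edges, weights = [], []
        for u, v, data in g.edges(data=True):
            if u == v:
                logger.warning("dropping self-loop at node %r", u)
                continue
            edges.append((idx[u], idx[v]))
            weights.append(float(data.get("weight", 1.0)))
        if semantics == "unweighted":
            weights = [1.0] * len(weights)
        return cls(nodes, np.array(edges), np.array(weights), semantics)


@dataclass
class SPLMatrix:
    """All-pairs shortest path lengths in weight units."""

    spl: np.ndarray
    spl_max: float


@dataclass(eq=False)
class Partition:
    """Hard assignment of every node to exactly one community."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        if not self.labels:
            raise GraphInputError("empty partition")

    @classmethod
    def from_communities(cls, communities) -> "Partition":
        """Build from an iterable of node collections (one per community)."""
        labels = {}
        for ci, comm in enumerate(communities):
            for node in comm:
                labels[str(node)] = str(ci)
        return cls(labels)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def sizes(self) -> Counter:
        return Counter(self.labels.values())

    def as_indices(self, nodes) -> np.ndarray:
        """Integer community labels aligned with a node ordering."""
        uniq = {lab: i for i, lab in enumerate(sorted(set(self.labels.values())))}
        try:
            return np.array([uniq[self.labels[str(v)]] for v in nodes], dtype=np.int64)
        except KeyError as exc:
            raise GraphInputError(f"node {exc.args[0]!r} missing from partition")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_list(path, semantics: str = "unweighted") -> WeightedGraph:
    """Read a whitespace-separated ``u v [w]`` edge list.

    Duplicate ``(u, v)``/``(v, u)`` lines collapse to a single edge with the
    last weight winning; self-loop lines are dropped with a warning.  A file
    without a weight column yields an unweighted graph regardless of the
    requested semantics.
    """
    node_index: dict[str, int] = {}
    nodes: list[str] = []
    edge_weight: dict[tuple[int, int], float] = {}
    saw_weight = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphInputError(f"{path}:{lineno}: expected 2 or 3 columns")
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                saw_weight = True
                try:
                    w = float(parts[2])
                except ValueError:
                    raise GraphInputError(f"{path}:{lineno}: unparsable weight {parts[2]!r}")
                if not np.isfinite(w) or w <= 0:
                    raise GraphInputError(f"{path}:{lineno}: nonpositive weight {w}")
            else:
                w = 1.0
            for x in (u, v):
                if x not in node_index:
                    node_index[x] = len(nodes)
                    nodes.append(x)
            if u == v:
                logger.warning("%s:%d: dropping self-loop %r", path, lineno, u)
                continue
            iu, iv = node_index[u], node_index[v]
            key = (min(iu, iv), max(iu, iv))
            if key in edge_weight:
                logger.warning("%s:%d: duplicate edge %s-%s, last weight wins", path, lineno, u, v)
            edge_weight[key] = w
    if not saw_weight:
        semantics = "unweighted"
    edges = np.array(list(edge_weight.keys()), dtype=np.int64).reshape(-1, 2)
    weights = np.array(list(edge_weight.values()), dtype=np.float64)
    return WeightedGraph(tuple(nodes), edges, weights, semantics)


def write_edge_list(graph: WeightedGraph, path) -> None:
    """Write ``u v w`` lines (12+ significant digits, LF endings)."""
    with open(path, "w", newline="\n") as fh:
        for (u, v), w in zip(graph.edges, graph.weights):
            fh.write(f"{graph.nodes[u]} {graph.nodes[v]} {float(w)!r}\n")


def read_membership(path) -> dict[str, str]:
    """Read a ``node label`` membership file into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphInputError(f"{path}:{lineno}: expected 2 columns")
            labels[parts[0]] = parts[1]
    return labels


def write_membership(labels: dict[str, str], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for node, lab in labels.items():
            fh.write(f"{node} {lab}\n")


# ---------------------------------------------------------------------------
# Topological quantities
# ---------------------------------------------------------------------------

def largest_connected_component(nodes, edges, weights, semantics) -> WeightedGraph:
    """Induced subgraph on the largest component of a possibly disconnected
    graph (ties broken toward the component holding the lexicographically
    smallest node identifier)."""
    nodes = tuple(str(n) for n in nodes)
    if not nodes:
        raise GraphInputError("empty graph")
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    weights = np.asarray(weights, dtype=np.float64).ravel()
    n = len(nodes)
    a = sp.coo_matrix(
        (np.ones(2 * len(edges)),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    ncomp, labels = connected_components(a, directed=False)
    sizes = np.bincount(labels, minlength=ncomp)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        # tie: component containing the smallest identifier
        rep = {c: min(nodes[i] for i in np.flatnonzero(labels == c)) for c in best}
        chosen = min(best, key=lambda c: rep[c])
    else:
        chosen = best[0]
    keep = np.flatnonzero(labels == chosen)
    remap = {old: new for new, old in enumerate(keep)}
    mask = np.array([labels[u] == chosen for u in edges[:, 0]])
    sub_edges = np.array([[remap[u], remap[v]] for u, v in edges[mask]], dtype=np.int64).reshape(-1, 2)
    return WeightedGraph(tuple(nodes[i] for i in keep), sub_edges, weights[mask], semantics)


def degree_stats(graph: WeightedGraph) -> tuple[float, int]:
    """Mean degree ``2E/N`` and modal degree (ties -> smallest value)."""
    degs = graph.degrees()
    mean = 2.0 * graph.n_edges / graph.n_nodes
    counts = Counter(degs.tolist())
    top = max(counts.values())
    mode = min(k for k, c in counts.items() if c == top)
    return mean, int(mode)


def shortest_path_matrix(graph: WeightedGraph) -> SPLMatrix:
    """Exact all-pairs shortest path lengths (Dijkstra per source).

    Distance semantics use the weights as edge lengths (floored at
    ``EDGE_LENGTH_FLOOR``); unweighted graphs use hop counts.  Proximity
    weights have no length interpretation and must be converted first.
    """
    if graph.semantics == "proximity":
        raise ContractError("shortest paths need distance-like or unit weights")
    if graph.semantics == "unweighted":
        lengths = np.ones_like(graph.weights)
    else:
        lengths = np.maximum(graph.weights, EDGE_LENGTH_FLOOR)
    a = graph.adjacency(lengths)
    spl = dijkstra(a, directed=False)
    if not np.all(np.isfinite(spl)):
        raise ConnectivityError("infinite shortest path: graph not connected")
    spl = 0.5 * (spl + spl.T)  # exact symmetry against float noise
    np.fill_diagonal(spl, 0.0)
    return SPLMatrix(spl, float(spl.max()))


def mean_edge_weight(graph: WeightedGraph) -> float:
    """Arithmetic mean of the edge weights (the IERW monitoring quantity)."""
    if graph.n_edges < 1:
        raise GraphInputError("graph has no edges")
    return float(graph.weights.mean())
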