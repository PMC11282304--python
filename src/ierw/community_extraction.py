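"""Turning IERW outputs into partitions.

The headline extractor is :func:`threshold_partition`: sort the edge
weights, trim 5% off each end of the list, cut at the largest gap between
consecutive weights, delete the edges on the "far" side of the midpoint
threshold (larger-than for distance weights, smaller-than for proximity
weights), and read the communities off the connected components.

For feeding IERW's weighted graphs to classic detectors, the weight
conversions are provided: distance → proximity via ``w̃ = 1/(w0 + w)`` and
the proximity shift ``w̃ = w0 + w`` (default w0 = 1) that benefits the
detectors after node2vec reweighting.  The detectors themselves (Louvain,
Infomap, asynchronous label propagation with the disconnected-label
post-split, and HDBSCAN on the cosine-distance matrix) are external
implementations behind thin adapters.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .embeddings import Embedding, pairwise_cosines
from .graph_core import ContractError, Partition, WeightedGraph

DETECTION_METHODS = ("louvain", "infomap", "label_propagation")


@dataclass
class ThresholdReport:
    sorted_weights: np.ndarray
    trimmed: int              # entries dropped from EACH end of the list
    gap_position: int         # gap between kept[i] and kept[i+1]
    threshold: float
    removed_edges: int
    partition: Partition


def _components_partition(graph: WeightedGraph, keep_mask: np.ndarray) -> Partition:
    n = graph.n_nodes
    e = graph.edges[keep_mask]
    a = sp.coo_matrix(
        (np.ones(2 * len(e)), (np.concatenate([e[:, 0], e[:, 1]]),
                               np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    _, labels = connected_components(a.tocsr(), directed=False)
    return Partition({graph.nodes[i]: str(labels[i]) for i in range(n)})


def threshold_partition(graph: WeightedGraph) -> tuple[Partition, ThresholdReport]:
    """Largest-gap weight thresholding.

    Steps: (1) sort the E edge weights ascending; (2) drop the ⌊0.05·E⌋
    smallest and ⌊0.05·E⌋ largest entries from the gap-search list, which
    bounds the removal between 5% and 95% of the links; (3) find the
    largest gap between consecutive remaining weights (first on ties) and
    set the threshold to the mean of its two flanking weights; (4) delete
    the edges strictly beyond the threshold (above it for distance
    weights, below it for proximity weights); (5) each connected component
    of the pruned graph is a community.
    """
    if graph.semantics == "unweighted":
        raise ContractError("weight thresholding needs distance or proximity weights")
    e = graph.n_edges
    if e < 2:
        raise ContractError("need at least 2 edges to threshold")
    order = np.sort(graph.weights)
    trim = int(np.floor(0.05 * e))
    kept = order[trim:e - trim] if trim else order
    gaps = np.diff(kept)
    gpos = int(np.argmax(gaps)) if len(gaps) else 0
    threshold = float(0.5 * (kept[gpos] + kept[gpos + 1])) if len(gaps) else float(kept[0])
    if graph.semantics == "distance":
        keep_mask = ~(graph.weights > threshold)
    else:
        keep_mask = ~(graph.weights < threshold)
    removed = int(e - keep_mask.sum())
    part = _components_partition(graph, keep_mask)
    return part, ThresholdReport(order, trim, gpos, threshold, removed, part)


# ---------------------------------------------------------------------------
# Weight conversions
# ---------------------------------------------------------------------------

def convert_distance_weights(graph: WeightedGraph, w0: float) -> WeightedGraph:
    """Distance → proximity: w̃ = 1/(w0 + w); small w0 emphasizes the
    near-zero intra-community distances IERW produces."""
    if graph.semantics != "distance":
        raise ContractError("conversion applies to distance-like weights")
    if w0 <= 0:
        raise ValueError("w0 must be positive")
    return graph.with_weights(1.0 / (w0 + graph.weights), "proximity")


def shift_proximity_weights(graph: WeightedGraph, w0: float = 1.0) -> WeightedGraph:
    """Proximity shift w̃ = w0 + w (w0 = 1 benefits the classic detectors
    on node2vec-reweighted graphs)."""
    if graph.semantics != "proximity":
        raise ContractError("shift applies to proximity-like weights")
    if w0 == 0:
        return graph
    return graph.with_weights(w0 + graph.weights, "proximity")


# ---------------------------------------------------------------------------
# External detectors
# ---------------------------------------------------------------------------

def _split_disconnected_labels(graph: WeightedGraph, communities) -> Partition:
    """Split every label class into its connected components (the label
    propagation post-step)."""
    idx = {v: i for i, v in enumerate(graph.nodes)}
    final = []
    for comm in communities:
        members = sorted(idx[str(v)] for v in comm)
        if not members:
            continue
        sub = set(members)
        pos = {m: i for i, m in enumerate(members)}
        mask = [(u in sub and v in sub) for u, v in graph.edges]
        e = graph.edges[np.array(mask, dtype=bool)]
        a = sp.coo_matrix(
            (np.ones(2 * len(e)),
             (np.concatenate([[pos[u] for u in e[:, 0]], [pos[v] for v in e[:, 1]]]),
              np.concatenate([[pos[v] for v in e[:, 1]], [pos[u] for u in e[:, 0]]]))),
            shape=(len(members), len(members)),
        )
        ncomp, labels = connected_components(a.tocsr(), directed=False)
        for c in range(ncomp):
            final.append([graph.nodes[members[i]] for i in np.flatnonzero(labels == c)])
    return Partition.from_communities(final)


def detect_with(graph: WeightedGraph, method: str, seed: int = 0) -> Partition:
    """Run an external community detector on the (proximity or unit) weights."""
    if graph.semantics == "distance":
        raise ContractError("convert distance weights before running detectors")
    weighted = graph.semantics == "proximity"
    if method == "louvain":
        import networkx as nx

        g = graph.to_networkx()
        comms = nx.community.louvain_communities(
            g, weight="weight" if weighted else None, seed=seed)
        return Partition.from_communities(comms)
    if method == "infomap":
        import igraph

        g = igraph.Graph(n=graph.n_nodes, edges=[tuple(e) for e in graph.edges])
        state = _random.getstate()  # igraph draws from Python's random module
        try:
            _random.seed(seed)
            clu = g.community_infomap(
                edge_weights=graph.weights.tolist() if weighted else None)
        finally:
            _random.setstate(state)
        return Partition.from_communities(
            [[graph.nodes[i] for i in c] for c in clu])
    if method == "label_propagation":
        import networkx as nx

        g = graph.to_networkx()
        comms = list(nx.community.asyn_lpa_communities(
            g, weight="weight" if weighted else None, seed=seed))
        return _split_disconnected_labels(graph, comms)
    raise ValueError(f"no implementation available for method {method!r}")


def hdbscan_on_embedding(emb: Embedding, min_cluster_size: int = 5) -> Partition:
    """HDBSCAN on the N×N cosine-distance matrix of the embedding.

    Noise points become singleton communities (similarity metrics need
    every node labeled).
    """
    if len(emb.nodes) < 4:
        raise ValueError("need at least 4 points to cluster")
    from sklearn.cluster import HDBSCAN

    dist = 1.0 - pairwise_cosines(emb)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    assert np.allclose(dist, dist.T) and np.all(np.diag(dist) == 0)
    labels = HDBSCAN(min_cluster_size=min_cluster_size, metric="precomputed",
                     allow_single_cluster=True, copy=True).fit_predict(dist)
    out = {}
    next_single = int(labels.max()) + 1 if labels.max() >= 0 else 0
    for i, lab in enumerate(labels):
        if lab == -1:
            out[emb.nodes[i]] = f"noise{next_single}"
            next_single += 1
        else:
            out[emb.nodes[i]] = str(int(lab))
    return Partition(out)
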