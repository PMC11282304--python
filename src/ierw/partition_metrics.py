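"""Evaluation metrics for embeddings and partitions.

* :func:`angular_separation_ratio` — ⟨Δθ⟩ over inter-community node pairs
  divided by ⟨Δθ⟩ over intra-community pairs, computed over all N(N−1)/2
  pairs of an embedding.  Rising values over IERW iterations are the
  method's footprint.
* :func:`ecs` — element-centric clustering similarity in its
  hard-partition closed form.  Each node i induces a cluster-affinity
  distribution (uniform over its groupmates, including itself); S_i is one
  minus half the L1 distance between i's affinities under the two
  partitions, and ECS is the mean of S_i.  The random-walk restart
  probability α only matters for overlapping/hierarchical clusterings and
  is provably inert here (kept in the signature for fidelity).
* :func:`ari` / :func:`ami` — chance-corrected Rand index and mutual
  information, the latter normalized by the maximum of the two Shannon
  entropies (delegated to scikit-learn).
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .embeddings import Embedding
from .graph_core import GraphInputError, Partition

logger = logging.getLogger(__name__)

DEFAULT_ECS_ALPHA = 0.9


class MetricError(ValueError):
    """Metric undefined for the given inputs."""


def _aligned_labels(p1: Partition, p2: Partition) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = set(p1.labels), set(p2.labels)
    if n1 != n2:
        raise GraphInputError("partitions cover different node sets")
    nodes = sorted(n1)
    return p1.as_indices(nodes), p2.as_indices(nodes)


def angular_separation_ratio(emb: Embedding, partition: Partition,
                             block: int = 512) -> float:
    """⟨Δθ⟩_inter / ⟨Δθ⟩_intra over all node pairs (blocked computation)."""
    lab = partition.as_indices(emb.nodes)
    if len(set(lab.tolist())) < 2:
        raise MetricError("separation ratio needs at least 2 communities")
    u = emb.unit_positions()
    n = u.shape[0]
    sum_intra = sum_inter = 0.0
    cnt_intra = cnt_inter = 0
    for s in range(0, n, block):
        e = min(n, s + block)
        cos = np.clip(u[s:e] @ u.T, -1.0, 1.0)
        theta = np.arccos(cos)
        same = lab[s:e, None] == lab[None, :]
        upper = np.arange(n)[None, :] > np.arange(s, e)[:, None]
        m_intra = same & upper
        m_inter = (~same) & upper
        sum_intra += theta[m_intra].sum()
        cnt_intra += int(m_intra.sum())
        sum_inter += theta[m_inter].sum()
        cnt_inter += int(m_inter.sum())
    if cnt_intra == 0:
        raise MetricError("no intra-community pair: ratio undefined")
    mean_intra = sum_intra / cnt_intra
    mean_inter = sum_inter / cnt_inter
    if mean_intra == 0.0:
        raise MetricError("zero mean intra-community angle: ratio undefined")
    return float(mean_inter / mean_intra)


def ecs(p1: Partition, p2: Partition, alpha: float = DEFAULT_ECS_ALPHA) -> float:
    """Element-centric similarity of two hard partitions (closed form).

    S_i = 1 − ½·[ o·|1/n₁ − 1/n₂| + (n₁ − o)/n₁ + (n₂ − o)/n₂ ] where n₁
    and n₂ are the sizes of i's clusters and o their overlap.
    """
    if not 0.0 < alpha < 1.0:
        raise MetricError("alpha must lie in (0, 1)")
    l1, l2 = _aligned_labels(p1, p2)
    n = len(l1)
    c1 = np.bincount(l1)
    c2 = np.bincount(l2)
    # contingency counts o for each (cluster1, cluster2) pair
    key = l1.astype(np.int64) * (l2.max() + 1) + l2
    overlap_of_pair = {}
    for k, cnt in zip(*np.unique(key, return_counts=True)):
        overlap_of_pair[int(k)] = int(cnt)
    o = np.array([overlap_of_pair[int(k)] for k in key], dtype=np.float64)
    n1 = c1[l1].astype(np.float64)
    n2 = c2[l2].astype(np.float64)
    s = 1.0 - 0.5 * (o * np.abs(1.0 / n1 - 1.0 / n2)
                     + (n1 - o) / n1 + (n2 - o) / n2)
    return float(s.mean())


def ari(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index (pair counting, chance corrected)."""
    l1, l2 = _aligned_labels(p1, p2)
    return float(adjusted_rand_score(l1, l2))


def ami(p1: Partition, p2: Partition) -> float:
    """Adjusted mutual information, normalized by max(H₁, H₂)."""
    l1, l2 = _aligned_labels(p1, p2)
    if len(set(l1.tolist())) == 1 and len(set(l2.tolist())) == 1:
        logger.warning("both partitions trivial: AMI defined as 1")
        return 1.0
    return float(adjusted_mutual_info_score(l1, l2, average_method="max"))
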