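"""Seeded skip-gram-with-negative-sampling kernels for node2vec.

Single-threaded numba kernels: weighted first-order random walks over a
CSR adjacency, and an SGD word2vec trainer (negative sampling, dynamic
context window, linearly decaying learning rate).  Everything is driven by
explicit integer seeds so embeddings are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _bisect(arr, lo, hi, target):
    # first index j in [lo, hi) with arr[j] >= target
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] < target:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def random_walks(indptr, indices, cumw, walks_per_node, walk_length, seed):
    """Weight-proportional random walks, ``walks_per_node`` starts per node.

    ``cumw`` holds the within-row cumulative transition weights aligned
    with ``indices``.
    """
    np.random.seed(seed)
    n = indptr.shape[0] - 1
    walks = np.empty((n * walks_per_node, walk_length), dtype=np.int32)
    row = 0
    for _ in range(walks_per_node):
        for start in range(n):
            cur = start
            walks[row, 0] = cur
            for step in range(1, walk_length):
                lo, hi = indptr[cur], indptr[cur + 1]
                total = cumw[hi - 1]
                r = np.random.random() * total
                j = _bisect(cumw, lo, hi, r)
                if j >= hi:
                    j = hi - 1
                cur = indices[j]
                walks[row, step] = cur
            row += 1
    return walks


@njit(cache=True)
def train_sgns(walks, window, n_nodes, dim, epochs, negative, alpha0, noise_cdf, seed):
    """Train skip-gram embeddings on the walk corpus.

    ``noise_cdf`` is the cumulative unigram^(3/4) noise distribution used
    for negative sampling.  Returns the input (word) vectors.
    """
    np.random.seed(seed)
    syn0 = ((np.random.random((n_nodes, dim)) - 0.5) / dim).astype(np.float32)
    syn1 = np.zeros((n_nodes, dim), dtype=np.float32)
    n_walks, walk_len = walks.shape
    neu1e = np.empty(dim, dtype=np.float32)

    # rough pair count for the linear learning-rate schedule
    total_pairs = epochs * n_walks * walk_len * min(window, walk_len - 1)
    processed = 0
    min_alpha = 1e-4 * alpha0

    for _ in range(epochs):
        order = np.random.permutation(n_walks)
        for oi in range(n_walks):
            walk = walks[order[oi]]
            for i in range(walk_len):
                center = walk[i]
                b = 1 + np.random.randint(window)  # dynamic window in [1, window]
                jlo = i - b if i - b > 0 else 0
                jhi = i + b + 1 if i + b + 1 < walk_len else walk_len
                for j in range(jlo, jhi):
                    if j == i:
                        continue
                    ctx = walk[j]
                    alpha = alpha0 * (1.0 - processed / (total_pairs + 1.0))
                    if alpha < min_alpha:
                        alpha = min_alpha
                    processed += 1
                    for k in range(dim):
                        neu1e[k] = 0.0
                    for neg in range(negative + 1):
                        if neg == 0:
                            target = ctx
                            label = 1.0
                        else:
                            r = np.random.random()
                            target = _bisect(noise_cdf, 0, n_nodes, r)
                            if target >= n_nodes:
                                target = n_nodes - 1
                            if target == ctx:
                                continue
                            label = 0.0
                        f = 0.0
                        for k in range(dim):
                            f += syn0[center, k] * syn1[target, k]
                        if f > 6.0:
                            s = 1.0
                        elif f < -6.0:
                            s = 0.0
                        else:
                            s = 1.0 / (1.0 + np.exp(-f))
                        g = (label - s) * alpha
                        for k in range(dim):
                            neu1e[k] += g * syn1[target, k]
                            syn1[target, k] += g * syn0[center, k]
                    for k in range(dim):
                        syn0[center, k] += neu1e[k]
    return syn0
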