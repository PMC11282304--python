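"""Estimating the community count C and the embedding dimension d.

The number of communities is read off the spectrum of the symmetric
normalized Laplacian ``I − D^{-1/2} A D^{-1/2}``: on an idealized graph of
C well-separated blocks the C smallest eigenvalues sit near zero, with a
large gap to the rest.  We locate the largest gap among the K smallest
eigenvalues and count the nonzero eigenvalues below it.  Because a
connected graph always contributes exactly one zero eigenvalue, that
literal count equals C − 1 on ideal block graphs; by default one is added
back so that the estimate tracks the block count itself (``literal=True``
switches to the raw count).

Matrix-factorization backends then embed in d = C − 1 dimensions (floored
at 2: a one-dimensional embedding collapses every angle to 0 or π);
node2vec uses a fixed d = 64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_core import WeightedGraph

ZERO_TOL = 1e-8
NODE2VEC_DIM = 64
MATRIX_BACKENDS = ("le", "trexpic", "iso", "iso-raw")


class SpectralError(RuntimeError):
    """Eigenvalue computation failed or was inconsistently parameterized."""


@dataclass
class SpectralSelection:
    eigenvalues: np.ndarray
    zero_tol: float
    gap_index: int
    C_est: int
    d: int


def _sym_normalized_laplacian(graph: WeightedGraph) -> sp.csr_matrix:
    a = graph.adjacency()
    deg = np.asarray(a.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise SpectralError("zero-strength node in Laplacian")
    dinv = sp.diags(1.0 / np.sqrt(deg))
    n = graph.n_nodes
    return (sp.identity(n) - dinv @ a @ dinv).tocsr()


def default_n_eigenvalues(n_nodes: int) -> int:
    """How many small eigenvalues to inspect for the gap.

    Must exceed the plausible community count: benchmark graphs with
    minimum community size m admit up to N/m communities, so the window
    scales linearly with N (N/8 covers size-10 communities with margin)
    with a floor of 50 for small graphs.
    """
    return int(min(n_nodes - 1, max(50, round(n_nodes / 8))))


def normalized_laplacian_spectrum(graph: WeightedGraph, K: int | None = None) -> np.ndarray:
    """K smallest eigenvalues of the symmetric normalized Laplacian, ascending.

    Proximity weights enter the Laplacian directly; unweighted graphs use
    the 0/1 adjacency.  Distance weights are accepted as-is (the estimate
    is made once, on the initial — typically unweighted — graph).
    """
    n = graph.n_nodes
    if K is None:
        K = default_n_eigenvalues(n)
    if not 1 <= K <= n - 1:
        raise SpectralError(f"K={K} out of range for N={n}")
    lap = _sym_normalized_laplacian(graph)
    if n <= 200 or K >= n - 2:
        vals = np.linalg.eigvalsh(lap.toarray())[:K]
    else:
        # shift-invert around 0 (the matrix is PSD; shift keeps it factorizable)
        vals = spla.eigsh(lap, k=K, sigma=-1e-6, which="LM",
                          return_eigenvectors=False)
        vals = np.sort(vals)
    return np.clip(vals, 0.0, None)


def estimate_communities(eigenvalues: np.ndarray, zero_tol: float = ZERO_TOL,
                         literal: bool = False) -> int:
    """Community count from the largest eigengap (first maximizer on ties)."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise SpectralError("need at least 3 eigenvalues")
    gaps = np.diff(lam)
    g = int(np.argmax(gaps)) + 1  # gap sits between lam[g-1] and lam[g]
    nonzero_below = int(np.sum(lam[:g] > zero_tol))
    return nonzero_below if literal else nonzero_below + 1


def choose_dimension(backend: str, C_est: int) -> int:
    """Embedding dimension per backend: d = max(2, C − 1), or 64 for node2vec."""
    if backend == "node2vec":
        return NODE2VEC_DIM
    if backend in MATRIX_BACKENDS:
        return max(2, int(C_est) - 1)
    raise ValueError(f"unknown backend {backend!r}")


def select_dimension(graph: WeightedGraph, backend: str,
                     K: int | None = None, zero_tol: float = ZERO_TOL,
                     literal: bool = False) -> SpectralSelection:
    """One-shot pipeline: spectrum → gap → C estimate → dimension."""
    lam = normalized_laplacian_spectrum(graph, K)
    gaps = np.diff(lam)
    g = int(np.argmax(gaps)) + 1
    C_est = estimate_communities(lam, zero_tol, literal)
    return SpectralSelection(lam, zero_tol, g, C_est, choose_dimension(backend, C_est))
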