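"""The four embedding backends and the angular kernel.

Every backend maps a :class:`~ierw.graph_core.WeightedGraph` to an
:class:`Embedding` — an N×d matrix of Cartesian node positions.  The only
geometric quantity the iteration consumes afterwards is the angle between
position vectors,

    cos(Δθ_ij) = (y_i · y_j) / (‖y_i‖ ‖y_j‖),

which reads the same in the Euclidean backends (LE, ISO, node2vec) and the
native-hyperbolic one (TREXPIC), since both use Cartesian coordinates.

Backends
--------
``le``
    Laplacian Eigenmaps.  Distance weights are first converted to
    proximities via w' = exp(−w²/t) with t the squared mean distance
    weight, then the generalized eigenproblem L f = λ D f is solved and
    the eigenvectors of the d smallest nonzero eigenvalues become the
    coordinates.
``trexpic``
    Hyperbolic embedding of exponentialized shortest path lengths:
    X_ij = exp(−t/SPL_ij) is turned into a matrix of expected Lorentz
    products cosh(ζ·X_ij) whose truncated SVD yields one radial component
    (σ₁, u₁ — kept as a diagnostic) and d angular components.
``iso`` / ``iso-raw``
    Isomap via classical MDS on double-centered squared distances; the
    default variant exponentializes the shortest path lengths exactly as
    TREXPIC does, ``iso-raw`` uses them directly.
``node2vec``
    Weighted random walks fed to a skip-gram model with negative
    sampling (walk-transition probability proportional to the proximity
    weight of the edge).

LE/ISO/TREXPIC are deterministic up to the sign ambiguity of eigen- and
singular vectors; every factor column is canonicalized so its
largest-magnitude entry is positive, making repeated runs identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_core import ContractError, SPLMatrix, WeightedGraph, degree_stats, shortest_path_matrix

ZERO_TOL = 1e-8
#: Exponentialization constant prefactor shared by TREXPIC and exp-ISO:
#: sqrt(ln(1/0.9999)·ln(1/0.1)), to be multiplied by SPL_max.
_T_PREFACTOR = float(np.sqrt(np.log(1.0 / 0.9999) * np.log(1.0 / 0.1)))

BACKENDS = ("le", "trexpic", "iso", "iso-raw", "node2vec")


class EmbeddingError(RuntimeError):
    """Spectral/SVD failure or inconsistent embedding parameters."""


@dataclass
class BackendConfig:
    """Tunable constants of the embedding backends."""

    t_override: float | None = None       # exponentialization constant t
    zeta: float = 1.0                     # hyperbolic curvature K = −ζ²
    walks_per_node: int = 80
    walk_length: int = 10
    window: int = 10
    p: float = 1.0
    q: float = 1.0
    epochs: int = 5
    negative_samples: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.t_override is not None and self.t_override <= 0:
            raise ValueError("t_override must be positive")
        for name in ("zeta", "walks_per_node", "walk_length", "window", "p", "q",
                     "epochs", "negative_samples", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(eq=False)
class Embedding:
    """Cartesian node positions plus decomposition diagnostics."""

    nodes: tuple[str, ...]
    positions: np.ndarray          # (N, d)
    geometry: str                  # 'euclidean' | 'hyperbolic_native'
    backend: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[0] != len(self.nodes):
            raise EmbeddingError("positions must be N x d")
        if not np.all(np.isfinite(self.positions)):
            raise EmbeddingError("non-finite coordinates")

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def unit_positions(self) -> np.ndarray:
        """Row-normalized positions; raises on a zero-norm row."""
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms == 0):
            bad = self.nodes[int(np.argmin(norms))]
            raise ContractError(f"node {bad!r} sits at the origin: angle undefined")
        return self.positions / norms[:, None]


def cosine_of_angle(emb: Embedding, i, j) -> float:
    """cos Δθ between two nodes' position vectors, clamped into [−1, 1]."""
    ii = emb.nodes.index(str(i)) if not isinstance(i, (int, np.integer)) else int(i)
    jj = emb.nodes.index(str(j)) if not isinstance(j, (int, np.integer)) else int(j)
    yi, yj = emb.positions[ii], emb.positions[jj]
    ni, nj = np.linalg.norm(yi), np.linalg.norm(yj)
    if ni == 0 or nj == 0:
        raise ContractError("zero-norm position vector: angle undefined")
    return float(np.clip(yi @ yj / (ni * nj), -1.0, 1.0))


def pairwise_cosines(emb: Embedding) -> np.ndarray:
    """Full N×N matrix of clamped cos Δθ values."""
    u = emb.unit_positions()
    return np.clip(u @ u.T, -1.0, 1.0)


def _canonicalize_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def default_exponential_t(spl_max: float) -> float:
    """Default t of the exponentialized shortest-path transform."""
    return _T_PREFACTOR * spl_max


def _truncated_svd(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k singular values (descending) and left singular vectors."""
    n = mat.shape[0]
    if k > n:
        raise EmbeddingError(f"requested {k} singular values of an {n}x{n} matrix")
    if n <= 400 or k >= n - 1:
        u, s, _ = np.linalg.svd(mat, full_matrices=False)
        u, s = u[:, :k], s[:k]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        u, s, _ = spla.svds(mat, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s = u[:, order], s[order]
    return _canonicalize_signs(u), s


# ---------------------------------------------------------------------------
# Laplacian Eigenmaps
# ---------------------------------------------------------------------------

def _le_proximity_weights(graph: WeightedGraph) -> tuple[np.ndarray, float]:
    if graph.semantics == "proximity":
        raise ContractError("LE expects distance-like or unit weights")
    if graph.semantics == "unweighted":
        t = 1.0
        return np.full(graph.n_edges, np.exp(-1.0)), t
    t = float(graph.weights.mean()) ** 2
    return np.exp(-graph.weights**2 / t), t


def embed_le(graph: WeightedGraph, d: int) -> Embedding:
    """Laplacian Eigenmaps embedding in d Euclidean dimensions.

    Solves the generalized problem L f = λ D f through the symmetric
    substitution D^{-1/2} L D^{-1/2} g = λ g with f = D^{-1/2} g (so the
    eigenvectors automatically satisfy fᵀ D f = 1) and keeps the d
    smallest *nonzero* eigenvalues.  The single zero mode of a connected
    graph is removed by explicit deflation of its known eigenvector
    g₀ ∝ D^{1/2}·1 (Rayleigh–Ritz on the complement) rather than by a
    magnitude threshold: late IERW iterations drive genuine community
    eigenvalues arbitrarily close to zero, where any fixed tolerance would
    misclassify them.
    """
    n = graph.n_nodes
    if d >= n - 1:
        raise EmbeddingError(f"LE needs d < N-1 (got d={d}, N={n})")
    w_prox, t = _le_proximity_weights(graph)
    a = graph.adjacency(w_prox)
    deg = np.asarray(a.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise EmbeddingError("node with zero proximity strength")
    dinv = sp.diags(1.0 / np.sqrt(deg))
    lsym = (sp.identity(n) - dinv @ a @ dinv).tocsr()
    k = min(n - 1, d + 4)
    if n <= 300 or k >= n - 2:
        lam, g = np.linalg.eigh(lsym.toarray())
        lam, g = lam[:k], g[:, :k]
    else:
        lam, g = spla.eigsh(lsym, k=k, sigma=-1e-6, which="LM")
        order = np.argsort(lam)
        lam, g = lam[order], g[:, order]
    # deflate the zero mode and re-diagonalize on the orthogonal complement
    g0 = np.sqrt(deg)
    g0 /= np.linalg.norm(g0)
    block = g - np.outer(g0, g0 @ g)
    q = scipy.linalg.orth(block, rcond=1e-10)
    if q.shape[1] < d:
        raise EmbeddingError(
            f"only {q.shape[1]} nonzero eigenvalues available, need {d}")
    small = q.T @ (lsym @ q)
    mu, v = np.linalg.eigh(0.5 * (small + small.T))
    g_nz = q @ v[:, :d]
    f = (1.0 / np.sqrt(deg))[:, None] * g_nz
    f = _canonicalize_signs(f)
    return Embedding(graph.nodes, f, "euclidean", "le",
                     {"eigenvalues": np.clip(mu[:d], 0.0, None), "t": t})


# ---------------------------------------------------------------------------
# TREXPIC
# ---------------------------------------------------------------------------

def embed_trexpic(graph: WeightedGraph, d: int, t: float | None = None,
                  zeta: float = 1.0, spl: SPLMatrix | None = None) -> Embedding:
    """Hyperbolic embedding from exponentialized shortest path lengths."""
    if spl is None:
        spl = shortest_path_matrix(graph)
    if t is None:
        t = default_exponential_t(spl.spl_max)
    n = graph.n_nodes
    with np.errstate(divide="ignore"):
        x = np.exp(-t / spl.spl)
    np.fill_diagonal(x, 0.0)
    lorentz = np.cosh(zeta * x)
    u, s = _truncated_svd(lorentz, d + 1)
    if s[d] <= 0:
        raise EmbeddingError("not enough positive singular values")
    pos = u[:, 1:d + 1] * np.sqrt(s[1:d + 1])
    # radial diagnostic from the leading singular pair
    u1 = u[:, 0]
    sgn = 1.0 if u1.sum() >= 0 else -1.0
    radial = np.arccosh(np.maximum(1.0, np.sqrt(s[0]) * sgn * u1)) / zeta
    return Embedding(graph.nodes, pos, "hyperbolic_native", "trexpic",
                     {"singular_values": s, "t": t, "zeta": zeta, "radial": radial})


# ---------------------------------------------------------------------------
# Isomap
# ---------------------------------------------------------------------------

def embed_iso(graph: WeightedGraph, d: int, exponentialized: bool = True,
              t: float | None = None, spl: SPLMatrix | None = None) -> Embedding:
    """Isomap (classical MDS on graph distances), optionally exponentialized."""
    if spl is None:
        spl = shortest_path_matrix(graph)
    if exponentialized:
        if t is None:
            t = default_exponential_t(spl.spl_max)
        with np.errstate(divide="ignore"):
            dist = np.exp(-t / spl.spl)
        np.fill_diagonal(dist, 0.0)
    else:
        t = None
        dist = spl.spl
    n = graph.n_nodes
    # double centering: I = -1/2 · J (D∘D) J places the centroid at the origin
    d2 = dist * dist
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    inner = -0.5 * (d2 - row - col + d2.mean())
    u, s = _truncated_svd(inner, d)
    pos = u * np.sqrt(s)
    backend = "iso" if exponentialized else "iso-raw"
    return Embedding(graph.nodes, pos, "euclidean", backend,
                     {"singular_values": s, "t": t})


# ---------------------------------------------------------------------------
# node2vec
# ---------------------------------------------------------------------------

def embed_node2vec(graph: WeightedGraph, d: int = 64,
                   cfg: BackendConfig | None = None) -> Embedding:
    """node2vec embedding: weighted walks + skip-gram negative sampling."""
    from . import _sgns

    cfg = cfg or BackendConfig()
    if cfg.p != 1.0 or cfg.q != 1.0:
        raise NotImplementedError("only unbiased walks (p = q = 1) are supported")
    if graph.semantics == "distance":
        raise ContractError("node2vec expects proximity-like or unit weights")
    a = sp.csr_matrix(graph.adjacency())
    indptr = a.indptr.astype(np.int64)
    indices = a.indices.astype(np.int64)
    # within-row cumulative transition weights
    cumw = a.data.astype(np.float64).copy()
    for i in range(graph.n_nodes):
        lo, hi = indptr[i], indptr[i + 1]
        cumw[lo:hi] = np.cumsum(cumw[lo:hi])
    seed = int(cfg.seed) % (2**31 - 1)
    walks = _sgns.random_walks(indptr, indices, cumw, cfg.walks_per_node,
                               cfg.walk_length, seed)
    counts = np.bincount(walks.ravel(), minlength=graph.n_nodes).astype(np.float64)
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    pos = _sgns.train_sgns(walks, cfg.window, graph.n_nodes, d, cfg.epochs,
                           cfg.negative_samples, cfg.learning_rate, noise_cdf,
                           (seed + 1) % (2**31 - 1))
    return Embedding(graph.nodes, pos.astype(np.float64), "euclidean", "node2vec",
                     {"walks": walks.shape[0], "epochs": cfg.epochs, "seed": seed})


def embed(graph: WeightedGraph, backend: str, d: int,
          cfg: BackendConfig | None = None) -> Embedding:
    """Dispatch to a backend by name."""
    cfg = cfg or BackendConfig()
    if backend == "le":
        return embed_le(graph, d)
    if backend == "trexpic":
        return embed_trexpic(graph, d, t=cfg.t_override, zeta=cfg.zeta)
    if backend == "iso":
        return embed_iso(graph, d, exponentialized=True, t=cfg.t_override)
    if backend == "iso-raw":
        return embed_iso(graph, d, exponentialized=False)
    if backend == "node2vec":
        return embed_node2vec(graph, d, cfg)
    raise ValueError(f"unknown backend {backend!r}")
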