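# Methods

## The iteration

`run_ierw` alternates two steps on a connected, simple, undirected graph:

1. **Embed** the current weighted graph with one of four backends into a
   d-dimensional space (Cartesian coordinates in both the Euclidean and
   the native-hyperbolic case).
2. **Reweight** every *existing* edge from the angle between its
   endpoints' position vectors.  No new links are ever introduced, so the
   reweighting is linear in the number of edges.  Matrix backends receive
   distance-like weights `w = 1 − cos Δθ ∈ [0, 2]`; node2vec receives
   proximity-like weights `w = exp(t·[cos Δθ − 1]) ∈ (0, 1]` with
   `t = 10·κ̄/κ̂` (mean over modal degree, computed once from the fixed
   topology).

The loop monitors the mean edge weight w̄ and stops when its relative
change `|w̄_cur − w̄_prev|/w̄_cur` drops to `tol = 0.001` (first checked
between the first and second reweighting), or after `max_iter = 20`
iterations.  A mean weight of exactly zero (all nodes angularly
coincident) is a fixed point of the weighting and is treated as converged,
with a warning.

Two schedules are used deliberately:

* **Convergence schedule** (the default): everything that consumes the
  final weights — thresholding, detector pipelines — uses the `tol=0.001`
  stop.  At that point community recovery is already saturated.
* **Full schedule** (20 iterations, `tol` effectively disabled): the
  separation-*ratio* keeps growing for several iterations after w̄ has
  stabilized, because near-zero intra-community weights contribute almost
  nothing to the relative change of w̄.  Experiments that measure the
  saturated angular separation therefore run the full schedule.

## Embedding backends

**Laplacian Eigenmaps (`le`).**  Distance weights are converted to
proximities by `w' = exp(−w²/t)` with `t = (mean distance weight)²`
(recomputed each iteration, since the weights change; an unweighted graph
gives the uniform `e^{−1}`).  The generalized problem `L f = λ D f`
(`L = D − A` on the proximities) is solved through the symmetric
substitution `D^{-1/2} L D^{-1/2}`, dense below N=300 and by shift-invert
Lanczos above.  The d eigenvectors of the smallest *nonzero* eigenvalues
are the coordinates.  The zero mode of a connected graph is removed by
explicit deflation of its analytically known eigenvector `g₀ ∝ D^{1/2}·1`
(projection + Rayleigh–Ritz re-diagonalization) rather than by an
eigenvalue threshold: in late iterations the genuine community eigenvalues
fall below any fixed tolerance (down to ~e^{−80}), where a threshold rule
would discard exactly the informative directions.

**TREXPIC (`trexpic`).**  Shortest path lengths (Dijkstra; weights as
lengths, floored at 1e−10) are exponentialized, `X_ij = exp(−t/SPL_ij)`
with the default `t = sqrt(ln(1/0.9999)·ln(1/0.1))·SPL_max`, converted to
expected Lorentz products `cosh(ζ·X_ij)` (ζ = 1, curvature −1), and the
truncated SVD supplies coordinates: column ℓ is `sqrt(σ_{ℓ+1})·u_{ℓ+1}`,
ℓ = 1…d.  The leading pair (σ₁, u₁) encodes radial positions and is kept
as a diagnostic `r_i = arccosh(max(1, sqrt(σ₁)·s·u₁(i)))/ζ` (s makes u₁
predominantly positive); the iteration itself uses only angles, so the
exact radial convention has no effect on the results.

**Isomap (`iso`, `iso-raw`).**  Classical MDS: the squared-distance
matrix is double-centered, `I = −½·J(D∘D)J`, and the top-d SVD gives
`y_i(ℓ) = sqrt(σ_ℓ)·u_ℓ(i)` with the centroid at the origin.  The default
variant exponentializes the shortest path lengths with the same `t`
formula as TREXPIC; `iso-raw` uses them directly (and is exact on line
metrics, which the tests exploit).

**node2vec (`node2vec`).**  First-order weighted random walks (the
unbiased p = q = 1 case; transition probability proportional to the
proximity weight), 80 walks per node of length 10, feed a skip-gram model
with negative sampling: window 10 (dynamic, word2vec-style), 5 negative
samples from the unigram^(3/4) noise distribution, 5 epochs, initial
learning rate 0.025 with linear decay.  The trainer is a single-threaded
numba kernel driven entirely by explicit seeds, so runs are
bit-reproducible; per-iteration seeds derive from `config.seed + k` so the
walks differ across IERW iterations but the trace is reproducible.

**Determinism and signs.**  Eigen- and singular vectors are defined up to
sign; every factor column is flipped so that its largest-magnitude entry
is positive.  This makes the matrix backends exactly deterministic.
Degenerate eigenspaces remain defined only up to rotation, so oracle tests
compare subspaces (principal angles), not columns.

## Choosing the dimension

The community count C is estimated once, on the initial graph, from the
spectrum of the symmetric normalized Laplacian `I − D^{-1/2} A D^{-1/2}`:
locate the largest gap among the K smallest eigenvalues and count the
nonzero eigenvalues below it, plus one for the zero mode of a connected
graph (so that an ideal C-block graph yields exactly C; a literal count
without the +1 is available via `literal=True`).  K defaults to
`min(N−1, max(50, N/8))` — the window must exceed the largest plausible
community count, which is N/m_min for benchmarks with minimum community
size m_min = 10.  Matrix backends then use `d = max(2, C − 1)`; node2vec
always uses d = 64 (its SGD training is insensitive to d, and large d
costs little).

The d ≥ 2 floor keeps the angular kernel informative (in d = 1 every
cosine is ±1), at a known price: when C = 2 the spare dimension lets one
community settle on two angular rays, and threshold extraction can
over-split two-community graphs.  For C ≥ 3 the floor is inactive.

## Community extraction

**Weight thresholding.**  Sort the E weights ascending, drop the
⌊0.05·E⌋ smallest and ⌊0.05·E⌋ largest entries from the gap-search list
(bounding the removal between 5% and 95% of the links), cut at the largest
gap between consecutive weights (first on ties — conservative for distance
semantics), set the threshold to the midpoint of the flanking weights, and
delete the edges strictly beyond it (above for distance weights, below for
proximity).  Connected components of the pruned graph are the communities.
If all weights are equal, every gap is zero and nothing is removed: one
community.

**Detector adapters.**  Louvain (networkx, top level), Infomap
(igraph, two-level map equation), and asynchronous label propagation
(networkx) followed by splitting every label class into its connected
components.  Detectors expect proximity weights; IERW's distance weights
are converted by `w̃ = 1/(w0 + w)` first.  The package default is
`w0 = 0.05`: a small w0 amplifies the near-zero intra-community distances
that IERW produces, which is what lets Louvain escape its resolution
limit on the reweighted graphs.  node2vec's proximity weights are shifted
by `w̃ = 1 + w` before detection, which measurably helps all three
detectors.  HDBSCAN runs on the full N×N matrix of cosine distances
`1 − cos Δθ` as a precomputed dissimilarity (min_cluster_size 5,
single-cluster solutions allowed); noise points become singleton
communities so that partition metrics stay well defined.

## Synthetic benchmarks

**Planted partition.**  C = N/m equal blocks; from the mixing parameter μ
(expected fraction of a node's neighbours outside its block) and the mean
degree κ̄: `κ̄_out = μ·κ̄`, `κ̄_in = κ̄ − κ̄_out`, `p_out = κ̄_out/((C−1)·m)`,
`p_in = κ̄_in/(m−1)`.  Default parameters: N = 1000, m = 50 (20
communities), κ̄ = 20.  Generation delegates to networkx's
`planted_partition_graph`; disconnected samples are resampled with a
shifted seed (up to 100 times — at μ = 0 the blocks are provably disjoint
and the generator raises).

**Stochastic block model.**  Arbitrary block sizes and a symmetric
probability matrix M, via networkx; used for demos and the eigengap
stress tests.

**LFR.**  Implemented in-package: node degrees from a truncated continuous
power law (tail exponent γ = 2, cut at κ_max = 50, lower cutoff solved so
the expected mean is κ̄ = 20, sequences rejected until the sample mean is
within 2%); community sizes from a truncated power law (β = 3 on
[10, 100]) adjusted to sum to N; internal stub counts `round((1−μ)·k)`
capped at community size − 1, with community assignment by
first-fit-decreasing over random feasible choices; intra-community graphs
realized by Havel–Hakimi plus seeded double edge swaps (exact degree
sequences, randomized); external stubs matched globally with iterative
re-pairing that removes self-loops, duplicates and within-community
pairs.  The generator hits the requested mixing to within ~0.01–0.02
across μ ∈ [0.1, 0.9] and the requested mean degree to within 2%.

What the generators emulate — controlled mixing, heterogeneous degrees and
community sizes (LFR) — is what drives the method; what they do not
emulate includes overlapping communities, degree correlations, weighted or
directed topologies, and the noisy, partially annotated ground truth of
real networks.  Passing tests therefore demonstrate correct mechanics and
the expected behaviour *under these models*, not performance guarantees on
arbitrary real data (real networks are supported through the edge-list and
membership readers).

## Metrics

* **Angular separation ratio** — mean Δθ over all inter-community node
  pairs divided by mean Δθ over intra-community pairs, over all N(N−1)/2
  pairs; cosines are clamped to [−1, 1] before `arccos`.  Values around
  1e8 are the float64 ceiling: once intra-community cosines round to 1,
  the smallest representable angles are ~1e−8 rad.
* **ECS** — element-centric similarity in its hard-partition closed form:
  `S_i = 1 − ½[o·|1/n₁ − 1/n₂| + (n₁−o)/n₁ + (n₂−o)/n₂]` per node,
  averaged.  The restart parameter α only matters for overlapping or
  hierarchical clusterings; it is kept in the signature and provably inert
  here (a test asserts α-independence).
* **ARI / AMI** — scikit-learn's chance-corrected implementations, AMI
  normalized by the maximum of the two Shannon entropies; the exact
  permutation-model E[MI] is cross-checked against a direct hypergeometric
  summation in the tests.  Two single-cluster partitions are defined as
  AMI 1 (identical trivial partitions), with a warning.

## Numerical choices and degenerate inputs

* Distance weights are floored at 1e−10 (reweighting and shortest paths):
  angularly coincident endpoints would otherwise produce zero-length edges
  and undefined `exp(−t/SPL)` values.
* Gap ties in thresholding and eigengap selection take the first (lowest)
  position — deterministic and conservative.
* In late LE iterations, the proximity conversion can underflow for
  strongly mixed graphs (`exp(−4/t)` with t below ~0.006, i.e. mean
  distance weight below ~0.075 — only reachable for μ well under 0.1); the
  loop then reports an embedding failure with the iteration index.
* Duplicate edges (last wins) and self-loops (dropped) in input files are
  logged, never silent.

## Desk-scale experiment profile

The default experiment profile runs 10 realizations per parameter point
and the test suite uses 2–5 seeds per check; standard errors scale as
1/√n, so curve shapes and orderings are stable under this reduction.
The separation-shape tests run the benchmarks at N = 250 (N = 150 with 6
iterations for node2vec, whose training dominates the runtime); the
checks that depend on absolute scale — the 1e7+ saturated ratio, the
20-community plateau, the Louvain resolution-limit comparison — keep
N = 1000.

## Known limitations

* Second-order node2vec walks (p ≠ 1 or q ≠ 1) are not implemented; the
  defaults used throughout are p = q = 1.
* The C = 2 over-splitting artifact of the d ≥ 2 floor, above.
* μ = 0 benchmarks are disconnected by construction and raise, since every
  backend requires a connected input.
* The eigengap estimate degrades for strong mixing (μ ≳ 0.5), where the
  matrix backends then embed with an unreliable d; this mirrors the
  regime where community recovery fails anyway.
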