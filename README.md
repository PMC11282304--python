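# ierw — iterative embedding and reweighting for community detection

Communities — groups of nodes with many internal and few external links —
are often easy to *see* in a graph embedding but hard to cut out cleanly:
when the mixing between groups is strong, the embedded clusters overlap.
`ierw` implements an iterative remedy.  The graph is embedded, every link
weight is rewritten from the angle Δθ between its endpoints' position
vectors,

```
cos(Δθ_ij) = (y_i · y_j) / (‖y_i‖ ‖y_j‖),
```

and the weighted graph is embedded again.  Intra-community links shrink
(distance-like weights `w = 1 − cos Δθ`) or strengthen (node2vec's
proximity weights `w = exp(t·[cos Δθ − 1])`, `t = 10·κ̄/κ̂`), so each round
makes the communities more pronounced, until the mean link weight w̄
stabilizes (`|w̄_cur − w̄_prev|/w̄_cur ≤ 0.001`, at most 20 iterations).
After a few rounds the angular gap between communities becomes so large
that a trivially simple extractor works: sort the weights, cut at the
largest gap, and read the communities off the connected components.

The package is aimed at network scientists studying community structure in
biological and social graphs, and provides:

* **Embedding backends** — Laplacian Eigenmaps (generalized eigenproblem
  `L f = λ D f` on exponential proximities `exp(−w²/t)`), TREXPIC
  (hyperbolic embedding via SVD of Lorentz products
  `cosh(ζ·exp(−t/SPL))`), Isomap (classical MDS on shortest path lengths,
  raw or exponentialized), and node2vec (seeded weighted random walks +
  skip-gram with negative sampling).
* **Dimension selection** — the number of communities C estimated from the
  largest eigengap of the normalized Laplacian; matrix backends embed in
  `d = C − 1` dimensions (node2vec uses a fixed d = 64).
* **Synthetic benchmarks** — planted-partition, stochastic-block-model and
  LFR generators with planted ground truth (power-law degrees and
  community sizes, calibrated mixing parameter μ).
* **Extraction & scoring** — largest-gap weight thresholding, adapters for
  Louvain / Infomap / asynchronous label propagation (with the
  disconnected-label post-split) / HDBSCAN on cosine distances, and the
  evaluation metrics: angular separation ratio ⟨Δθ⟩_inter/⟨Δθ⟩_intra,
  element-centric similarity (ECS), adjusted Rand index and adjusted
  mutual information (max-entropy normalization).

## Worked example

```python
from ierw import (PPParams, generate_pp, IERWConfig, run_ierw,
                  threshold_partition, ecs, ari)
from ierw.experiment import separation_curve

# 1000 nodes, 20 planted communities of 50, mean degree 20, 10% mixing
graph, truth = generate_pp(PPParams(N=1000, m=50, mean_degree=20.0,
                                    mu=0.1, seed=0))
trace = run_ierw(graph, IERWConfig(backend="trexpic", seed=1))
print("iterations:", trace.n_iterations, trace.stop_reason)
print("separation ratio per iteration:",
      [round(r, 1) for r in separation_curve(trace, truth)])
pred, report = threshold_partition(trace.final_graph)
print("communities:", pred.n_communities,
      "ECS:", round(ecs(truth, pred), 3), "ARI:", round(ari(truth, pred), 3))
```

prints

```
iterations: 4 tolerance
separation ratio per iteration: [2.9, 16.5, 2290.2, 6623592.5]
communities: 20 ECS: 1.0 ARI: 1.0
```

The angular separation between the planted communities grows by six
orders of magnitude in four iterations; cutting the final weights at their
largest gap recovers all 20 planted communities exactly.

The same pipeline is scriptable from the shell:

```bash
ierw benchmark pp --mu 0.1 --seed 0 --out g.edges --truth t.tsv
ierw run --input g.edges --backend trexpic --seed 1 --out-weights w.edges
ierw communities --weights w.edges --semantics distance --method threshold --out pred.tsv
ierw eval --truth t.tsv --pred pred.tsv
```

## Layout

```
src/ierw/graph_core.py            graph container, I/O, shortest paths
src/ierw/synthetic_benchmarks.py  PP / SBM / LFR generators
src/ierw/spectral_dimension.py    eigengap community count, dimension choice
src/ierw/embeddings.py            LE, TREXPIC, ISO, node2vec + angular kernel
src/ierw/ierw_loop.py             the embed → reweight → test-convergence loop
src/ierw/community_extraction.py  weight thresholding, detector adapters
src/ierw/partition_metrics.py     separation ratio, ECS, ARI, AMI
src/ierw/experiment.py            experiment grids with tidy results tables
src/ierw/cli.py                   `ierw` command-line interface
docs/methods.md                   model details, defaults, limitations
```
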