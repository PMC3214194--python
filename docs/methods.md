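# Methods

## Model and procedure

`coexnet` infers an undirected weighted co-expression network from a
samples × probesets expression matrix and provides deterministic,
filter-aware exploration of that network. The inference chain assumes the
matrix is already preprocessed (e.g. normalized log-intensities); no
normalization of the expression values is performed here.

**Discretization.** Each probeset column is binned by rank into `nbins`
equal-frequency bins. The column is stably sorted (ties keep original
sample order) and split into consecutive blocks; with n samples the first
`n mod nbins` blocks hold `⌈n/nbins⌉` samples and the rest `⌊n/nbins⌋`.
Consequences worth knowing: (a) the binning is invariant under any
strictly monotone transform of a tie-free column, so only ranks matter;
(b) a run of tied values may straddle a bin boundary — a constant column
is still split across bins by sample order. This keeps the procedure
deterministic without a data-dependent tie policy. Default
`nbins = ⌊√n⌋`; the square-root heuristic balances resolution against the
variance of the plug-in estimator at microarray-scale sample counts
(n ≈ 20–200). `nbins` must not exceed n.

**Mutual information.** The plug-in (maximum-likelihood) estimator on the
discretized columns, in nats, computed with
`sklearn.metrics.mutual_info_score`. The MI matrix stores column entropies
on its diagonal for auditing; MRNET never reads the diagonal. Plug-in MI
is biased upward at small n — acceptable here because MRNET only compares
MI values against each other, and all pairs share the same bias regime.
Alternative estimators (Miller–Madow, shrinkage) are deliberately not
offered.

**MRNET.** For each target Y, MRMR forward selection over all other
variables: the first pick maximizes relevance I(X;Y) and scores that
relevance; each later pick maximizes
`u_j = I(X_j;Y) − mean_{X_k ∈ S} I(X_j;X_k)` (S = selected set) and
scores that u_j. Design choices where the convention was open:

* selection runs to exhaustion, so every ordered pair gets a directed
  score and the raw (possibly negative) scores are preserved in
  `MrnetResult.directed_scores` as an audit trail;
* negative scores are clamped to zero only in the final undirected weight
  `w_ij = max(0, max(s_{i→j}, s_{j→i}))`;
* arg-max ties break to the lowest column index, making the whole
  procedure deterministic.

**Normalization.** An optional, separate step divides all weights by the
global maximum (all-zero matrices pass through). Raw MRMR scores are
unbounded above, so a bounded [0, 1] scale is what makes threshold values
portable; it is optional because the raw scores are the faithful output
of the scoring step.

## Exploration semantics

* **Filters.** `apply_filter` removes edges with weight < threshold
  (i.e. keeps weight ≥ threshold), then removes nodes whose degree *in the
  edge-filtered graph* is below the cutoff in a single pass, then — if a
  cluster selection is active — keeps only nodes of the chosen connected
  components of the edge-filtered graph. The single-pass degree rule
  mirrors a one-shot view filter and is intentionally *not* idempotent
  (on the path a–b–c with min_degree=2, b survives as an isolate; a second
  application would remove it); `iterate_degree=True` switches to k-core
  pruning, which is idempotent. The weight and cluster filters are
  idempotent on their own.
* **Clusters** are connected components, always recomputed on the filtered
  view — excluded edges never hold a cluster together. Labels are
  consecutive integers by decreasing size, ties by smallest member id.
* **Deepness neighborhoods** are BFS balls of radius d around the selected
  node set (induced subgraph), with `"max"` meaning the union of the
  selected nodes' components. The ball is computed on the filtered graph
  when a filter is active.
* **Shortest paths** are unweighted (hop count): MRNET weights are
  similarities, not distances, and no weighted path cost is defined.
  Among equal-length paths the lexicographically smallest node-id
  sequence is returned; unreachable pairs yield an explicit no-path
  result rather than an exception.
* **Girvan–Newman** removes exactly one edge per iteration — the one with
  the highest unweighted shortest-path edge betweenness, recomputed each
  iteration; ties go to the lexicographically smallest (source, target)
  pair. Removing m = |E| edges yields all singletons.
* **Statistics.** The diameter of a disconnected network is the maximum
  eccentricity within components (a literal ∞ would make the statistic
  useless on filtered views); the local clustering coefficient is
  2T/(k(k−1)) with the convention 0 for degree < 2; weight histograms use
  equal-width bins over [min, max] (default 20 bins), with a single bin
  for a degenerate range.
* **Layouts.** Circle layout places nodes sorted by id equally spaced on
  the unit circle from angle 0 counterclockwise. Fruchterman–Reingold
  uses the standard forces (repulsion k²/d, attraction d²/k, k = √(1/n),
  linear cooling) from a seeded random start via `networkx.spring_layout`
  on a sorted copy of the graph, so identical (network, iterations, seed)
  input is bitwise reproducible regardless of node insertion order.

## Serialization

GraphML is written with sorted nodes, edges and keys so repeated writes
are byte-identical; weights use Python's shortest round-trip float repr,
so reads recover them exactly. On read, the weight key is the edge key
named `weight` (case-insensitive, type double), else the first
double-typed edge key, else every edge defaults to 1.0; unknown keys
survive as string attributes; directed files are folded to undirected,
keeping the larger weight of a duplicated pair (a hard error would reject
valid third-party files for what is always an undirected co-expression
relation here); a dangling edge endpoint is an error. Adjacency tables
use the R `write.table` dialect (quoted header of column names, quoted
row names, tabs); on read the matrix must be symmetric to 1e−9, otherwise
it is symmetrized entrywise by the maximum with a warning.

## Synthetic benchmark

`simulate_expression` plants co-expression modules with a single-factor
linear model: one latent standard-normal factor per module per sample;
each module gene is `loading·factor + N(0, noise_sd²)`; noise genes are
pure N(0, 1). Defaults: 50 samples, 3 modules × 10 genes, 10 noise genes,
loading 2.0, noise sd 0.5 — giving within-module correlations of about
loading²/(loading² + noise_sd²) ≈ 0.94, a strong but not degenerate
signal. The generator emulates none of the structure of real microarray
data beyond correlated blocks: no probe effects, batch effects, skewed
intensity distributions or heavy-tailed noise. Passing the recovery tests
therefore shows that the inference chain detects planted linear
dependency structure at realistic sample sizes, not that it is robust to
microarray artifacts.

The end-to-end check ranks all gene pairs by inferred weight and compares
within-module pairs against all other pairs via the Mann–Whitney AUC;
with the defaults and a fixed seed the pipeline reaches AUC ≈ 0.94 and a
roughly ninefold gap between mean within- and between-module weights (the
exact numbers for a given seed are computed by `scripts/acceptance.py`
and the test suite, never stored).

## Numerical and degenerate-input choices

* MI is always in nats; tolerances in the oracle-agreement tests are
  1e−12 (scalar MI) and 1e−9 (MRNET, betweenness).
* `normalize_weights` of an all-zero matrix is the identity.
* An empty network is a valid I/O object but rejected by `diameter` and
  the layouts, where no meaningful answer exists.
* Weight histograms with zero edges return empty counts; a single-valued
  weight range returns one bin.
* All randomness (synthetic data, random networks, FR layout) flows
  through explicit integer seeds into `numpy.random.default_rng` /
  seeded networkx; nothing reads global RNG state.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: the
benchmark is 50 samples × 40 genes (780 gene pairs), oracle comparisons
use up to a few hundred random instances of ≤ 12 nodes, and brute-force
path enumeration stays at ≤ 10 nodes. These sizes make the exhaustive
oracles exact and the whole suite run in seconds; the library itself has
no such limits (inference is O(p²·n) in probesets and samples, and
Girvan–Newman O(m²·n) in edges, which is the practical ceiling for very
large graphs).

## Known limitations

* MRNET weights are comparable within one network but not across
  datasets unless normalized.
* Girvan–Newman with full betweenness recomputation is quadratic in edge
  count and intended for filtered subnetworks, not genome-scale graphs.
* The GraphML reader targets the attribute subset the toolkit writes
  (typed keys, defaults, nested graphs ignored); visual-extension
  namespaces (e.g. yEd) are not preserved.
* Annotation handling is a local TSV join; no live database lookups.
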