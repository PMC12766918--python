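# Methods

This note documents the models, statistics, defaults, and numerical
choices behind `netkin`, and what the synthetic benchmarks do and do not
establish about real data.

## Canonical network model

Networks are undirected, simple, and optionally weighted. Normalization
is deliberately opinionated so every downstream matrix is reproducible:

* node order is **lexicographic by id** — all matrix row indices derive
  from it, making results independent of input file ordering;
* directed inputs are symmetrized (an arc contributes an undirected
  edge; anti-parallel arcs collapse with weights summed). Citation-style
  graphs are therefore clustered on their undirected skeletons;
* self-loops are dropped with a warning — a loop carries no information
  about community co-membership;
* parallel/duplicate edges collapse with weights summed.

Symmetrization and collapsing are idempotent, so normalizing a
normalized network is the identity (property-tested).

The edge-list dialect writes one edge per line (`u<TAB>v[<TAB>weight]`)
and one bare token per isolated node, so edge lists round-trip networks
with isolated nodes. The `.gpickle` format is a pickled graph and is
non-portable across library versions; use cyjs/GraphML for exchange.

## Annotation matrix and the statistical universe

The membership matrix is binary CSC, nodes × terms, rows in canonical
node order. Term sizes are counted **after** intersection with the
network; terms outside `[min_size, max_size]` are dropped (default
`min_size=2` — a singleton term cannot be overrepresented beyond
triviality; default `max_size=N`). Members absent from the network are
excluded and counted.

The default universe is **all network nodes**. Both conventions found in
the enrichment literature are supported: `annotated_universe=True`
restricts N (and every cluster size n) to nodes carrying at least one
annotation. The choice shifts all p-values monotonically; it is recorded
in the matrix and applied consistently by every test, including the
permutation null.

## Overrepresentation tests

For a cluster of size n, universe N, term size K, overlap k, with 2×2
cells a=k, b=n−k, c=K−k, d=N−n−K+k:

* **hypergeometric** — exact upper tail P(X ≥ k), computed via `scipy`'s
  log-space survival function;
* **binomial** — upper tail of Binomial(n, K/N) at k; an approximation
  that treats cluster membership as independent draws;
* **chi-squared** — Pearson statistic N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)],
  1 df, no continuity correction. The **enrichment** p is half the χ²₁
  upper tail when ad > bc and 1.0 otherwise. Rationale: ad > bc is
  algebraically equivalent to k > nK/N (observed above expectation), and
  the full two-tailed χ² tail exceeds 0.5 for weak positive association,
  which would contradict the direction reported by the exact tests; the
  halved tail is the standard one-sided z-test on a 2×2 table. Degenerate
  tables (a zero margin) return (0, 1) with a warning;
* **permutation** — the null uniformly shuffles which node holds which
  annotation row, preserving both term sizes and cluster sizes. Under
  this exchangeable unit the null distribution of k is *exactly*
  hypergeometric, which gives a sharp internal consistency check
  (asserted in the tests). The estimator is add-one,
  p = (1 + #{k_r ≥ k_obs}) / (1 + R), so p is never 0 and the test is
  valid at any R.

All four tests are computed for every (cluster, term) pair in one
vectorized pass: the count matrix is the sparse product of the cluster
indicator with the membership matrix (dense clusters × terms, never
nodes × terms), and each permutation replicate is an O(N + nnz) scatter-add.
This is what lets the chi-squared path run on a 250 000-node /
500 000-edge network with 1000 terms in under a second of statistics
time on one CPU.

Multiple testing: Benjamini–Hochberg (default) or Bonferroni across all
(cluster, term) pairs, or `none` — the convention for raw-threshold
analyses such as "P < .01, permutation test". Adjusted p-values are
floored at the raw p. Depletion (lower-tail) p-values are available but
off by default.

**Discreteness and type-I calibration.** Exact tests on discrete counts
are conservative: P(p < α) ≤ α, with a real gap when term sizes are
small (for a size-5 term the achievable p-values are few and jumpy). The
end-to-end null benchmark (scale-free network, topology-independent
terms, Louvain, hypergeometric, α = 0.05) therefore demonstrates type-I
**control** — the observed significant-pair rate (≈ 0.023 pooled over 50
seeds) never exceeds α beyond Monte-Carlo error — rather than exact
equality with α, which no exact test can deliver under heavy-tailed term
sizes. This is asserted as `rate ≤ α + 3·SE` with a sanity floor.

## Community detection

Native implementations, all with seeded determinism (visit orders are
seeded shuffles; every tie breaks toward the smallest community id or
lexicographically smallest node):

* **Louvain** — local moving plus aggregation, resolution-γ modularity
  Q = Σ_c [W_c/m − γ(d_c/2m)²]. Moves require strictly positive gain
  (tolerance 1e−12), so Q never falls below the singleton partition's.
  On graphs small enough to enumerate all set partitions it reaches the
  global optimum in ≥ 90% of seeded instances (tested; it is a
  heuristic, so occasional misses are expected and recorded).
* **Label propagation** — asynchronous, weighted plurality, smallest
  label on ties; labels cannot cross connected components.
* **Greedy modularity** — CNM-style agglomeration, merging the pair with
  the largest positive ΔQ = 2(e_ij − γa_i a_j); ties by smallest id
  pair; stops at no positive gain.
* **Markov Clustering** — column-stochastic transition matrix with unit
  self-loops (the classic default; it guarantees aperiodicity), then
  alternating expansion (power e, default 2) and inflation (entrywise
  power r, default 2, then column renormalization), with entry pruning
  below 1e−5 and convergence when successive matrices differ by ≤ 1e−8
  in max-norm (non-convergence raises, carrying the last residual).
  Attractor rows define clusters; nodes attracted to several systems go
  to the lowest-id cluster (logged). Columns that lose all mass to
  pruning are re-seeded with identity, which keeps every node assigned.

Leiden, Spinglass, and Walktrap are not re-implemented; they are
delegated to `python-igraph`/`leidenalg` behind a registered-backend
contract, and a capability error lists the native options when the
backend is absent. Partitions are canonically renumbered (clusters
ordered by smallest contained node) so identical clusterings compare
equal regardless of algorithm internals.

Weighted graphs: modularity-based methods and MCL use edge weights
directly; label propagation uses weighted plurality.

## Domains and uniqueness

A cluster is significant when at least one term falls below α (on
adjusted p by default; on raw p when correction is `none`, matching
raw-threshold conventions). Its display label is its single best term;
the top-k list and the full significant-term list are retained.

"Unique" clusters: each significant cluster claims the union of its
significant terms' member nodes; nodes claimed by ≥ 2 clusters are
removed everywhere, and a cluster is unique if ≥ `min_remaining`
(default 1) nodes survive. Hard partitions are disjoint by construction,
so claims are built from term members — the place overlap can actually
arise; `mode="partition"` uses the cluster node sets directly, for
externally supplied (possibly overlapping) cluster files. The rule is
explicit and configurable because published analyses rarely state theirs.

## Layout-based evaluation

Computed on 2-D coordinates (layout seed recorded; external coordinates
accepted): compactness = mean pairwise intra-cluster distance (singleton
→ 0), separation = minimum centroid distance, silhouette
s = (b−a)/max(a,b) with the usual conventions (singleton or fully
coincident → 0). All three are invariant under rigid motions;
compactness and separation scale linearly under uniform scaling,
silhouette is scale-free (property-tested).

Mann–Whitney U: exact by full enumeration of rank assignments when
n₁+n₂ ≤ 12 with no ties; otherwise the normal approximation with the
standard tie-corrected variance and a 0.5 continuity correction. The
two-sided p is twice the smaller tail, capped at 1.

Because these metrics depend on the layout seed, absolute silhouette
values from any particular published analysis are not reproducible
without that seed; the package asserts *relative* properties instead
(a correct planted partition beats a random one in ≥ 95% of replicates).

## Synthetic benchmarks — what they emulate

* **Scale-free generator**: preferential attachment seeded with a
  complete graph on max(3, m+1) nodes. With m = 2 this makes the edge
  count closed-form, |E| = 3 + 2(n−3) = 2n − 3 — the twice-as-many-
  edges-as-nodes regime used for scalability benchmarking — and the
  graph connected by construction.
* **Null annotations**: term sizes i.i.d. from a truncated discrete
  power law, exponent 1.5 on [5, n/10] (1000 terms by default). The
  exponent and range are this package's stated operationalization of a
  GO-BP-like heavy-tailed size distribution — published analyses do not
  give parameters — and the distribution object is pluggable
  (`lognormal` included). Members are uniform without replacement,
  independent of topology: a pure null.
* **Planted fixture**: a 4×25 stochastic block model, p_in = 0.5,
  p_out = 0.02 (within-block mean degree 12 versus 1.5 across), with one
  signal term covering a seeded 80% subset of each block plus 20 decoy
  terms of 5–15 uniform nodes.

What passing these benchmarks shows: the statistics are exact against
enumeration, the permutation engine matches its analytic null, clustering
recovers strong planted structure, and the full pipeline is calibrated
and deterministic. What they do **not** show: performance on real
interaction networks, whose communities overlap, whose annotations
correlate with degree, and whose term tables have ontology structure —
none of which the null generators emulate.

## Problem sizes in the shipped checks

The test suite and acceptance script choose sizes that exercise every
contract while staying desk-scale: exhaustive enumeration up to N = 12;
permutation R = 10⁴ on 100-node fixtures; 50-seed null calibration at
n = 2000 with 1000 terms; 100-seed planted recovery; one 250 000-node /
~500 000-edge chi-squared run that checks the sparse-path memory
contract (the only dense array is clusters × terms). The acceptance
script repeats the headline computations at moderate replicate counts
(25 planted replicates, 10 null seeds) so a full from-scratch rerun
completes in seconds.

## Known limitations

* Louvain/greedy are heuristics; only small-graph optimality is asserted
  statistically, not guaranteed.
* MCL's hard-partition interpretation discards overlap information
  (overlapping attractors are logged, not exported).
* The chi-squared and binomial tests are approximations; for small
  clusters or rare terms prefer the hypergeometric or permutation test.
* The permutation null treats nodes as exchangeable; it does not
  preserve degree–annotation correlation. Degree-aware nulls are out of
  scope.
* KDE contours assume enough members for a 2-D density; tiny or
  degenerate clusters get hull/capsule fallbacks, which outline but do
  not estimate density.
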