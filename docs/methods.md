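# Methods

## Model and procedure

A flow graph is a DAG with strictly positive edge weights, exactly one
source `s` (indegree 0), exactly one sink `t` (outdegree 0), and flow
conservation at every other vertex.  A flow decomposition is a set of
distinct weighted `s`–`t` paths whose per-edge weight sums equal the flow; a
path is *w-safe* (`w > 0`) when in every decomposition the paths containing
it carry total weight ≥ `w`, and *safe* when it is w-safe for some positive
`w`.  Safety is decided by the *excess flow* `f_P`: the first-edge weight
minus the flow leaking out at internal vertices (equivalently, the last-edge
weight minus the flow entering at internal vertices; the two agree by
conservation and the implementation asserts this in integer mode).  `P` is
w-safe iff `f_P ≥ w`; a single edge has `f_P = f(e) > 0`, so every edge is
safe.

Enumeration of all *maximal* safe paths works on any flow decomposition,
because every safe path must appear inside some decomposition path.  The
package seeds the scan with the *simple peeling* decomposition (repeatedly
take the globally minimum-residual edge, extend it through positive-residual
edges to `s` and `t`, peel at the minimum weight; each iteration zeroes at
least one edge, so ≤ m paths).  On each decomposition path a two-pointer
scan advances the right pointer while the window's excess stays positive,
emits a window when the right pointer stalls past the previously emitted
right end (suppressing nested windows), then advances the left pointer.
Excess is updated in O(1) per pointer move via the extension deltas
(`f_in(v) − f(u,v)` at the start, `f_out(u) − f(u,v)` at the end), both
nonnegative by conservation, so excess is monotone under extension.

A window maximal *within its host* need not be maximal in the graph: its
safe extension lives on another host.  Deduplication therefore removes not
only duplicates and prefixes/suffixes but **arbitrary interior-substring
containments**, using an Aho–Corasick automaton over edge-id sequences
(edge-ids keep parallel edges unambiguous).  After dedup the expanded set
equals exactly the maximal safe paths of the graph: any surviving window is
safe and inextensible, and any maximal safe path survives as a window on
some host.  The result is stored concisely (`P_c`): per host, the minimal
subpath spanning each run of edge-sharing windows, plus window offsets.

Baselines: *greedy-width* repeatedly removes a maximum-bottleneck `s`–`t`
path (widest-path DP over a topological order); *extended unitigs* grow
every unitig — including single edges — left through unit-indegree vertices
and right through unit-outdegree vertices.  Extension steps have zero
excess-flow delta, so every extended unitig is safe with excess equal to its
seed edge's flow, and (after substring dedup) each embeds in some maximal
safe path.  *Funnels* — DAGs where no merge vertex (indegree ≥ 2) reaches a
fork vertex (outdegree ≥ 2), the same-vertex case included — are detected by
O(n + m) reachability from the merge set; funnels have a unique flow
decomposition and all methods are trivially perfect on them, so benchmark
datasets exclude them by default.

## Metrics

All metrics compare vertex sequences after stripping the artificial global
source/sink; the metrics layer rejects parallel-edge graphs, where vertex
sequences would be ambiguous.  *Weighted precision*: total length of
reported paths that are subpaths of some ground-truth transcript, over total
reported length; vacuously 1 when nothing is reported.  *Maximum relative
coverage*: per transcript, the longest single common contiguous stretch with
any reported path (longest-common-substring DP; segments are never merged),
relative to transcript length, averaged over transcripts.  *F-score*:
harmonic mean; aggregate tables recompute it from the stratum-mean precision
and coverage columns.  Lengths count vertices in node units or per-vertex
base counts in base units.  Strata: simple (2 ≤ k ≤ 10) and complex
(k > 10), with k the number of ground-truth transcripts.

## Synthetic data

`simulate_splice_instance` draws an ordered exon backbone (10–50 exons by
default), `k` distinct transcripts as increasing exon subsequences (each
exon retained with probability 0.7; duplicates redrawn), and per-transcript
abundances `round(1000 · X) + 1` with `X ~ LogNormal(μ = −4, σ = 2)`.  The
lognormal location/scale follow the read-simulator convention this protocol
descends from; a literal "variance −4" is impossible, so the parameters are
interpreted in log space and are configurable.  The `+1` integerization
keeps all weights positive integers so excess-flow arithmetic is exact;
a float mode preserves raw draws.  Superimposing the weighted transcripts
between a global source and sink yields a graph whose ground truth is a
flow decomposition by construction.  Exon base lengths are uniform in
30–1000.  Dataset generation draws `k` uniformly from [2, 35] and excludes
funnels by rejection.  Fixed seeds make instances byte-reproducible (one
`numpy` generator, documented draw order).

What the generator does *not* emulate: sequencing errors, coverage
dips/noise (so conservation is exact), annotation-derived exon structure,
or realistic k distributions (real gene sets are heavily skewed to small
k).  Perfect precision of safe algorithms on these instances demonstrates
the safety guarantee under error-free flows, not robustness to noisy real
RNA-seq graphs, where the flow property itself fails.

The ladder families stress the output-size behaviour.  Both consist of a
chain A, a bipartite block C×D, and a chain B.  In the worst-case variant
every C×D edge carries unit flow and chain weights follow by conservation;
every full `s`–`t` path then has excess exactly 1, so each C×D edge induces
its own graph-spanning maximal safe path and `|P_c|` equals the
decomposition size `‖P‖`.  In the best-case variant (C×D at weight 2, the
edges `(a_{k−1}, a_k)` and `(b_1, b_2)` split into equal-flow parallel
pairs) the parallel split caps safe paths at O(1)-size windows around each
C×D edge plus four chain-long paths, so `|P_c|` stays proportional to
`n + m` while `‖P‖` grows superlinearly.  The exact weight placement is the
package's own calibration, validated against the brute-force oracle at
small k; the tested contracts are the asymptotic ones.

## Numerical and design choices

- Integer weights are kept as Python `int`s; every comparison (excess > 0,
  decomposition sums) is then exact.  Float inputs fall back to a relative
  tolerance of 1e-9 in validation.
- All tie-breaks (minimum-edge selection, extension choices, widest-path
  predecessors) use the smallest edge-id, so decompositions are
  deterministic without seeds.  The greedy-width tie rule is not fixed by
  the literature; other implementations may differ on ties.
- Safety of 0-edge paths is undefined and rejected; `w ≤ 0` is rejected.
- The brute-force oracle enumerates decompositions as sets of distinct
  integer-weighted paths in lexicographic path order (weight splits of the
  same path merge and are not double-counted), guarded to total flow ≤ 8
  and m ≤ 12.  It is the independent referee for the excess-flow
  characterization and the enumeration's completeness at small scale.
- Graphs with several sources/sinks are rejected by validation; an explicit
  augmentation helper adds a global source/sink carrying the boundary
  flows.

## Problem sizes used by the test battery

Oracle-based checks run on 200 random integer-flow DAGs within the guard
(total flow ≤ 6, m ≤ 10) plus hand-built fixtures; formulation and
incrementality identities on 10⁴ random paths in simulated instances;
funnel equivalence on 100 random funnels and 100 simulated non-funnels;
scaling on ladder sizes k ∈ {4, 8, 16}; and the dataset-level precision of
both safe algorithms on 200 simulated instances with k ∈ [2, 35].

## Known limitations

- The funnel ⇔ "extended unitigs are complete" equivalence is
  flow-dependent in one corner: a non-funnel whose only merge-to-fork
  witnesses are single vertices (merge and fork at the same vertex, no
  butterfly body edges) can, under balanced flows, have its extended
  unitigs coincide with the maximal safe paths.  The equivalence holds on
  the simulated splice instances the tests use; the corner case was found
  with the brute-force oracle on a 7-edge graph.
- The enumeration is O(‖P‖) safety updates but the expanded output can be
  Θ(mn²) in general; use the concise representation for large instances.
- The metrics layer requires simple graphs; evaluation of parallel-edge
  instances (which the enumeration itself supports) is out of scope.
- Wall-clock/memory benchmarking and sequencing-read simulation are not
  goals of this package.
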