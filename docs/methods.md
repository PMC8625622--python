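# Methods

## Model

The pipeline treats drug repurposing as a single-commodity maximum-flow
problem. The assumption is that a drug is promising for a disease when its
protein targets are *well connected* to the disease's risk genes — not
merely close in hops, but connected through edges that are themselves
reliable, where reliability is proxied by neighbourhood overlap. Three
modelling choices follow:

* **Edge capacity = topological overlap.** For an edge {x, y},
  `TOM(x, y) = (|N(x) ∩ N(y)| + 1) / min(|N(x)|, |N(y)|)` (the adjacent
  case of the general formula). Neighbour sets exclude the node itself;
  since the graph has no self-loops, x and y never appear in the
  intersection, so no further convention is needed. For an edge the
  denominator is ≥ 1 (each endpoint has at least the other as neighbour);
  this is asserted. TOM is computed only on actual edges — only edges carry
  flow — at O(edges · average degree) instead of O(n²). Edges with TOM = 0
  are kept with capacity 0 so topology-only baselines see the same graph.

* **Undirected edges as antiparallel arc pairs.** Interaction signal has no
  inherent direction, so each edge becomes two directed arcs of equal
  capacity. The arcs keep separate residuals (no merging), which the solver
  supports natively.

* **Non-restrictive dummy terminals.** The source arc of target t carries
  t's total real out-capacity and the sink arc of risk gene g carries g's
  total real in-capacity, so neither dummy arc binds before the node's own
  edges do. A node in both sets receives both arcs by default
  (`overlap_policy="both"`); `target_only` / `gene_only` are available
  because the literature gives no guidance either way.

## Solver

`push_relabel_maxflow` is a FIFO push-relabel implementation with
current-arc pointers: height(source) = |V|, source arcs saturated at start,
active nodes discharged in queue order, and a relabel to one above the
lowest residual neighbour when a node's arc list is exhausted. Arcs are
indexed in lexicographic (from, to) order, which fixes the discharge order
and makes output deterministic across runs and platforms. Capacities are
reals (TOM weights), so every comparison uses an epsilon (default 1e-12)
below which excess and residual are treated as zero. Gap and
global-relabelling heuristics are omitted: at the problem sizes this package
targets (up to a few times 10⁵ arcs) the plain algorithm is fast enough, and
optional code paths that change no default behaviour would only add surface.

`reference_maxflow` (Edmonds–Karp, BFS augmentation) shares only the arc
indexing with the production solver and serves as the in-package oracle; the
test suite additionally cross-checks against networkx's solver and, on
networks of ≤ 12 nodes, against exhaustive enumeration of all 2^(n−2) cuts.

Per-arc flows of a maximum flow are not unique in general. The package's
contract is the total flow value and the source-arc flows used for ranking;
in degenerate networks even source-arc flows can tie, and the deterministic
arc order then fixes the reported split. Rankings expose this only through
tie-breaks, which are lexicographic everywhere.

## Ranking

Targets are sorted by descending source-arc flow. A drug's score is the
**maximum** flow among its targets that are in the ranked set (consistent
with reporting one target and one flow value per drug); `sum` and `mean`
aggregations are available via `drug_agg`. Drugs whose targets all fall
outside the ranked set are dropped with a logged count — only ranked targets
receive source arcs, so other interactions carry no flow information. Flow
values are reported both raw and as a fraction of the total flow, since
either scale is a defensible per-target score and published tables do not
disambiguate. All ties break lexicographically (targets by node ID, drugs by
drug ID), making every output invariant to input row order.

## Baselines

Degree (raw), closeness (Wasserman–Faust-corrected for disconnected
graphs), betweenness (unnormalised, endpoints excluded) and PageRank
(damping 0.85, tolerance 1e-10) run on the unweighted graph via networkx.
Random walk with restart is implemented in-package (no canonical library
variant exists): restart probability 0.5 to a uniform distribution over the
risk genes, power iteration to 1e-10, walkers on degree-0 nodes restart
immediately. PageRank/RWR parameters are config-exposed; the defaults follow
common practice, since no standard values exist for this application. All
five feed the same drug-ranking rule as the flow method.

## Synthetic data

The generator emulates the qualitative features the method depends on, not
any particular interactome's statistics:

* **Topology:** preferential attachment from an initial clique on m+1 nodes
  (m = `attachment_edges`, default 3 → mean degree ≈ 6 at n = 500), giving
  the hub-dominated, heavy-tailed degree distribution of real PPI networks.
  The edge count is exactly C(m+1, 2) + (n − m − 1)·m.
* **Risk module:** one connected *peripheral* community, grown from a
  minimum-degree seed by lowest-degree frontier expansion. Risk genes from
  association studies are rarely interactome hubs, and a hub-centred module
  would be reachable from everywhere, removing the flow competition the
  benchmark is meant to probe.
* **Targets and drivers:** `n_targets` (default 50) sampled uniformly
  outside the module; `n_drivers` (default 5) of them each gain
  `driver_boost` (default 10) new edges to distinct risk genes, making them
  genuinely high-throughput routes to the sink.
* **Drugs:** `n_drugs` (default 100) each carry 1–3 uniform targets; every
  driver is guaranteed at least one drug, attached to a *random* drug ID so
  lexicographic tie-breaking cannot systematically favour driver drugs under
  the null.

All randomness flows from one seed through named `numpy` generators; a fixed
seed yields byte-identical files. What passing benchmarks on these fixtures
does **not** show: robustness to false-positive interactions, study bias in
interactome coverage, literature-confirmed clinical relevance, or behaviour
on networks whose risk genes are themselves hubs.

## Benchmark and problem sizes

The planted-driver benchmark runs 20 independent replicates at n = 500,
boost = 10, scoring each method's precision@5 on driver drugs; the null
condition (boost = 0) is compared with the per-replicate hypergeometric
random expectation using a three-standard-error band over the replicates.
These sizes keep the whole comparison under a minute per condition on one
CPU while leaving the signal/noise separation unambiguous (flow ≈ 0.7–0.9
vs degree ≈ 0.3–0.4 across seeds; null ≈ random ≈ 0.18).

## Numerical and degenerate-input choices

* Solver epsilon 1e-12; test assertions on flow laws at 1e-9.
* `tom_similarity` rejects x = y and unknown nodes; readers reject empty
  files, malformed lines (with line numbers) and empty mapped node sets.
* Self-loops are dropped on read (their node is kept) with a warning;
  duplicate and reversed edge lines collapse.
* Reserved terminal IDs `__SDN__` / `__DDN__` collide with no gene symbol;
  a network already containing them is rejected.
* Network statistics report triangle counts under both conventions (each
  triangle once, and summed per-node incidences = 3×), since published
  tables are ambiguous about which they print.

## Known limitations

* Per-arc flow attributions are tie-broken, not canonical; two valid maximum
  flows can attribute throughput differently between targets sharing routes.
* The flow model is static: no dosage, binding affinity, or edge
  directionality (activation vs inhibition) enters the capacities.
* The benchmark's ground truth is structural (planted edges), a proxy for —
  not evidence of — clinical repurposing value.
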