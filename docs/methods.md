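# Methods

## Scope and model

`frontiernet` operates on finite directed graphs G(V, E) with real arc
weights w: E → ℝ, held in compressed sparse row (CSR) form: an `offsets`
array of length |V|+1 indexing concatenated `targets`/`weights` arrays.
Graphs enter as COO edge tables (`from`, `to`, `weight` records); undirected
networks — the common case for protein–protein interaction data — are
stored as symmetric directed CSR with two arcs per record (self-loops
once), so a single family of directed traversal kernels serves both cases.

Canonicalisation: within each vertex slice targets are sorted ascending,
ties between parallel edges broken by ascending weight. This fixes an
otherwise arbitrary adjacency order, making graph equality, transposition
round-trips and all traversal output deterministic. Parallel edges are
kept: BFS is insensitive to them and Bellman-Ford naturally relaxes all of
them, whereas collapsing (say, to the minimum weight) would silently
change shortest-path semantics for any other collapse rule.

## Frontier-based BFS

BFS proceeds level-synchronously with two frontiers: F1 holds the vertices
at the current depth, F2 collects their not-yet-visited neighbours. Because
several F1 members may reach the same neighbour in one step, F2 is
deduplicated before the swap; here deduplication is an exact membership
test (visited bitmap + `np.unique`), a hard no-duplicates guarantee rather
than a probabilistic one. Frontiers are emitted in ascending vertex order.
Depth is hop count; weights are ignored. The multi-source entry point runs
one independent sweep per source and returns an s×|V| depth matrix.
Unreachable entries carry a maximal-int sentinel, serialised as `inf`.

## Frontier-based Bellman-Ford SSSP

Each pass relaxes every arc leaving the current frontier
(`dist[v] ← min(dist[v], dist[u] + w)`); the next frontier is exactly the
set of vertices whose tentative distance improved — the only vertices whose
out-arcs can still improve anything. The sweep visits frontier vertices in
ascending order and reads the distance array live (Gauss–Seidel style);
this converges to the same fixed point as a frozen-snapshot sweep, in no
more passes, and the fixed point — not the pass count — is the contract.
The predecessor recorded among equal-cost parents is the last improving
write in this canonical order: implementation-defined but deterministic.

Negative arc weights are accepted. Without negative cycles the frontier
must empty within |V| passes (each pass extends the settled path prefix);
a frontier still active after |V| passes therefore proves a reachable
negative cycle and raises an error — the only semantics under which
"shortest path" remains well defined. Distances and predecessors are
returned as s×|V| matrices; with unit weights the distance matrix equals
the BFS depth matrix entry for entry (tested).

## Three-phase SCC decomposition

1. **Trimming.** A vertex with no active successor or no active
   predecessor cannot lie on a cycle within the active set; it is its own
   singleton SCC. Removal cascades to a fixed point, fully resolving any
   DAG. A self-loop counts as neither an active predecessor nor successor
   here — otherwise a vertex whose only cycle is its own loop would never
   trim despite being a trivial singleton component.
2. **Forward–backward.** The pivot is the active vertex maximising
   (active in-degree × active out-degree), a standard coverage-maximising
   heuristic, ties to the smallest index. Its SCC is the intersection of
   its forward and backward closures within the current set; the three
   residual sets (forward-only, backward-only, untouched) are SCC-closed
   and are each trimmed and processed independently in the next round.
   The number of rounds, `fb_rounds` (default 1), only shifts work between
   this phase and the next; the partition is identical for every value ≥ 0
   (tested at 0, 1, 3).
3. **Coloring.** On the residue: every vertex starts with its own index as
   its color; the maximum color propagates along arcs among active
   vertices to a fixed point. Every vertex whose color is unchanged is a
   pivot, and the backward closure restricted to its color class is one
   SCC; remove and repeat until nothing is active.

Component ids are canonicalised to the smallest vertex index in each
component, so output is independent of phase scheduling. On a symmetric
(undirected-origin) graph the partition coincides with connected
components, which the seed-subnetwork workflow relies on.

## Network-analysis workflows

* **Score filtering** keeps records with weight ≥ threshold and leaves the
  vertex universe intact (isolated vertices remain), matching how
  confidence thresholds (e.g. STRING's 0–1000 combined scores, commonly
  cut at 200 or 900) are applied to interaction networks.
* **Coexpression networks** compute pairwise Pearson correlation across
  samples for all gene pairs; a pair becomes an undirected edge weighted r
  when r ≥ t (signed mode) or |r| ≥ t (absolute mode, the default, since
  strong negative coexpression is usually informative too). Genes with
  zero variance or any missing value (listwise deletion) form no edges;
  at least 3 samples are required for r to be minimally meaningful.
* **Seed subnetwork** extraction takes the component containing a seed
  gene and induces its subgraph — the guilt-by-association neighbourhood
  used to hypothesise functions for an uncharacterised gene such as a
  lncRNA.
* **Path statistics** average the finite source→target shortest-path
  distances (target ≠ source), reporting finite/total pair counts so
  unreachable pairs are visible rather than silently dropped. Because
  shortest paths may leave a subnetwork, a subnetwork distance can only be
  ≥ the full-graph distance for the same pair — asserted per pair in the
  tests; the aggregate means are not comparable and are reported side by
  side instead.
* **Weight transforms** are explicit, never implicit: `one-minus-abs`
  (1 − |r|, correlations into distances) and `max-minus-score`
  (default ceiling 1000, confidence scores into distances). Path length
  over raw similarity weights is meaningless, so the choice is surfaced as
  a mandatory user decision.

## Synthetic data

The generators emulate the input classes of interaction-network studies at
desk scale, each fully determined by an integer seed through one
`numpy.random.default_rng` instance (no global state):

* **Erdős–Rényi** G(n, p), directed or undirected, unit weights — the
  neutral substrate for oracle cross-checks.
* **STRING-like networks**: preferential attachment (m edges per arriving
  vertex), giving the heavy-tailed degree distribution characteristic of
  real PPI networks, with integer scores uniform in 1–999 standing in for
  combined confidence scores. Real STRING networks have correlated,
  evidence-driven scores and community structure this generator does not
  model; passing tests demonstrate kernel correctness and workflow
  plumbing, not biological fidelity.
* **Planted-SCC digraphs**: blocks wired as directed Hamiltonian cycles
  plus random intra-block arcs (p_intra = 0.2), inter-block arcs only
  forward in block order (p_inter = 0.05), making the blocks exactly the
  SCCs and the condensation acyclic by construction.
* **Expression matrices**: gene i in module k is
  `mixing · z_k + sqrt(1 − mixing²) · ε_i` with z_k a per-module latent
  sample factor and ε independent standard normal, so within-module
  correlation is mixing² in expectation and exactly 1 at mixing = 1;
  background genes are pure noise. Module recovery is exercised at
  mixing 0.9 with 100 samples (expected r ≈ 0.81) against threshold 0.5.
  Real expression data has heavier tails, batch structure and overlapping
  modules; none of that is modelled.

## Numerical choices and degenerate inputs

* Distance comparisons in tests use 1e-9 relative tolerance; the kernels
  themselves use exact float comparison (`<`) for relaxation, as in any
  Bellman-Ford.
* Pearson r values are clipped to [−1, 1] to absorb floating-point
  overshoot before thresholding.
* Empty graphs, empty frontiers, isolated vertices, self-loops and
  parallel edges are all legal inputs with defined behaviour; empty edge
  *files* are rejected (more likely a pipeline error than a real network).
* Mean path distance over zero finite pairs is NaN, not 0 — silence would
  misreport a disconnected query as "distance zero".

## Problem sizes

Test suites run on seeded families of random instances: 100 graphs
(n ≤ 200) for each traversal oracle suite, 200 random digraphs (n ≤ 300)
plus 20 planted instances for SCC, 20 instrumented runs for frontier
semantics, 50 graphs for the unit-weight cross-check. The acceptance
script uses a 1500-vertex preferential-attachment network and a 75-vertex
planted digraph. These sizes exhibit all frontier dynamics (multi-level
propagation, duplicate collisions, multi-pass relaxation, all three SCC
phases active) while keeping the full suite in the order of seconds.

## Known limitations

* Kernels are sequential CPU implementations of frontier semantics; no
  attempt is made to emulate GPU memory layout or scheduling.
* No direction-optimising BFS, Δ-stepping, or incremental SCC maintenance.
* Missing expression values are handled by listwise gene deletion only.
* The CLI reads whole graphs into memory; practical scale is millions of
  arcs, not billions.
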