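# Methods

## Scope and model

`capnet` analyzes literature-curated directed signaling networks: nodes are
molecules or molecular events, edges are reported interactions with a
free-text kind label ("activates", "degrades", …).  Labels are opaque
identifiers — curators resolve synonyms upstream; the alias column of the
curated table is carried through but never applied.  Edge semantics
(activation vs. inhibition) are carried as labels only and never used
numerically.

Networks are simple directed graphs by default.  The build policy collapses
duplicate (source, target) pairs (keeping the first label, or concatenating
distinct labels with `|` when configured) and drops self-loops, recording
both counts in the network's provenance.  Rationale: shortest-path counting
— and therefore betweenness — is only well defined without multi-edges, and
every panel metric is degenerate on self-loops.  Nodes mentioned only in a
dropped self-loop remain in the node set (the node set is the union of all
sources and targets).

## Topology panel

* **Connected components** are weak components (components of the
  undirected projection).  A directed cascade with pure input nodes is never
  strongly connected, yet a single connected pathway should count as one
  network.
* **Path metrics** (diameter, characteristic path length) run in directed
  mode by default, over ordered pairs (u, v), u ≠ v, for which a path
  exists; unreachable pairs are excluded from both the maximum and the mean
  rather than treated as infinite.  This is the only convention that yields
  finite values on a directed pathway.  An undirected mode is exposed since
  desktop tools are not always explicit about which mode produced a printed
  value.
* **Clustering coefficient** uses the undirected form
  C_I = 2n_I/(k_I(k_I−1)) on the undirected projection; nodes with fewer
  than two neighbors contribute 0, and the network value is the unweighted
  mean over all nodes.
* **Average neighbor count** is the mean number of distinct neighbors on
  the undirected projection; on simple graphs without reciprocal edge pairs
  it equals 2E/N exactly.

## Centralities

**Betweenness** follows C_b(n) = Σ_{s≠n≠t} σ_st(n)/σ_st with endpoints
excluded, normalized by the number of node pairs excluding n within n's
(weak) component: (N−1)(N−2)/2 unordered pairs on undirected graphs and
(N−1)(N−2) ordered pairs on directed graphs.  The directed normalizer is
the ordered-pair count deliberately: dividing directed raw scores by the
unordered-pair count can exceed 1, and the [0, 1] range is part of the
metric's contract here.  Components with fewer than 3 nodes have no transit
pairs; their nodes score 0.

**Closeness** is the reciprocal of the mean shortest-path length to the
*reachable* node set (out-distances by default on directed graphs, with an
in-distance option).  Nodes that reach nothing — isolated nodes, pure sinks
in directed mode — score 0.  Reachable-set averaging keeps values in (0, 1]
and is what makes the isolated-node convention consistent.

**Degree-vs-clustering R²** is the coefficient of determination of the
least-squares line of per-node clustering coefficient on total degree.
Zero degree variance leaves the slope undefined → reported as undefined;
zero clustering variance (flat response) is defined as R² = 0, the
conservative "no explanatory power" reading.

## Scale-free fit

Degree histograms bin node counts N(k) over positive degrees k per mode
(in/out/total); zero-degree nodes are excluded from the bins (log 0 is
undefined) but counted in metadata.  The fit is ordinary least squares of
log₁₀ N(k) on log₁₀ k over the raw integer bins, no logarithmic binning or
smoothing: slope = γ, Pearson correlation of the logged points = r,
R² = r².  Counts N(k) rather than probabilities P(k) are fitted; the two
differ by a constant factor that moves only the intercept, never γ, r, or
R².  The fit requires at least two distinct positive degrees.  "Scale-free"
is reported as a qualitative classification (negative γ, high R², hubs with
near-zero clustering), never asserted as a statistical test — maximum-
likelihood estimation with goodness-of-fit p-values is out of scope by
design, as the regression procedure is the convention this panel reproduces.

## Hubs, bottlenecks, layers

**Hubs**: degree strictly greater than μ + σ, with μ and σ computed over
the degrees of all nodes.  Total degree (in + out) is the default mode, and
σ is the population standard deviation by default — the node set is the
whole population under study, not a sample; the sample option is retained
for sensitivity analysis.  On regular graphs σ = 0 and the strict
inequality flags nothing.

**Bottleneck score** BN(v) = Σ_s p_s(v): one shortest-path tree T_s per
root s, p_s(v) = 1 iff more than |V(T_s)|/4 of the tree's root-to-node
paths pass through v (strict inequality; |V(T_s)| includes the root).
Conventions the published rule leaves open, fixed here:

* Trees are BFS trees with deterministic tie-breaking — each node's parent
  is its lexicographically smallest equal-distance predecessor — so results
  are identical across runs and platforms.
* A path "meets" every vertex on it including its endpoint but excluding
  the root.  This makes the center of a star maximal (each leaf root sees
  all other paths cross the center), matching the reading of bottlenecks as
  information-flow controllers.
* On directed networks trees follow edge direction; roots reaching fewer
  than two other nodes contribute nothing (a two-node tree would otherwise
  trivially satisfy 1 > 2/4 for its only non-root vertex).
* The path-membership count of v equals the size of v's subtree in T_s,
  which is how scores are accumulated; the test oracle instead enumerates
  the paths explicitly and scans them.

**Hierarchical layers**: strongly connected components are condensed;
in-degree-0 super-nodes form layer 0 and every other super-node sits at its
longest-path depth from layer 0; member nodes inherit their component's
layer.  Longest-path (not shortest-path) depth guarantees that on acyclic
networks every edge descends strictly, the property that makes the layered
drawing read as information flow.  Within-layer ordering (edge-crossing
minimization) is a visual concern and is not implemented.

## Markov clustering

Canonical MCL on the undirected projection: add self-loops (weight 1.0),
column-normalize, then iterate expansion (matrix power 2) → inflation
(entrywise power, default 4, then renormalize) → prune entries below 1e-8,
until the maximum entry change drops below 1e-6 or 200 iterations.
Defaults beyond the inflation value are unconstrained by the procedure this
reproduces and were chosen once for determinism and desk-scale speed; all
are exposed in `MCLParams`.  Clusters are read from the attractor structure
of the limit matrix: attractors (non-zero diagonal) that attract one
another form one attractor system; a non-attractor node joins the system of
the attractor pulling it, resolving multiple pulls to the system containing
the lexicographically smallest attractor label.  There is no randomization
anywhere in the loop, so identical inputs and parameters give identical
partitions.

A property worth knowing: at inflation 4 the algorithm is deliberately
fine-grained, and moderately dense planted blocks (e.g. 8 nodes at
within-block edge probability 0.9) occasionally fragment into two attractor
systems even at the exact fixed point of the iteration — this is intrinsic
MCL behavior at high inflation, not a convergence artifact.  The measured
recovery rate over seeded planted-partition replicates is computed by
`scripts/acceptance.py` (`mcl_planted_recovery_pct`); typical values sit a
few percent below perfect recovery.

## Synthetic generators

The generators produce the study inputs, each deterministic given
(kind, parameters, seed), with the seeded PCG64 generator recorded in the
output provenance:

* `ba` — preferential attachment with n nodes, m edges per arrival, edges
  oriented new→existing so that early nodes accumulate in-degree, mirroring
  signaling convergence onto a few controllers.  Orientation is a
  documented convention, not a claim about mechanism.
* `planted_clusters` — k blocks of fixed size; each unordered node pair is
  drawn once (within-block probability p_in, between-block p_out) and
  oriented from the lower to the higher label.  The stated probabilities
  therefore are the edge densities of the undirected projection MCL
  operates on.
* `bridge` — two cliques sharing one articulation node, the canonical
  bottleneck topology.
* `exact_powerlaw` — the histogram N(k) = round(C·k^γ₀) over a chosen
  degree set, for exact fit recovery.
* `fixture_26sn` — a deterministic, synthetic 39-node/47-link directed
  acyclic network emulating a curated capacitation-signaling cascade at the
  level of its published summary constraints only: one weak component, a
  unique in-degree-0 source ("HCO3-"), three designated controller nodes
  with total degrees 13, 9, 7 that are the only nodes above the hub
  threshold, and no reciprocal edge pairs (so the average neighbor count is
  exactly 2·47/39 ≈ 2.410).  Its other panel values (diameter, path length,
  clustering, fit exponents) are whatever the construction yields — they do
  not emulate any real network, and nothing downstream assumes they do.

What passing tests on these inputs shows — and does not show: the
generators exercise the algorithms' contracts (exact recovery, invariants,
determinism) on networks with the right coarse statistics; they do not
reproduce the biology, noise structure, or curation artifacts of a real
literature-derived network, so conclusions about any real cascade still
require the real edge list.

## Numerical and degenerate-input choices

* Path metrics need ≥ 2 nodes; networks with no connected pair report
  undefined markers (`None`) rather than raising.
* Power-law fits with fewer than two distinct degrees raise in the library
  and are reported as undefined markers by the pipeline, which still exits
  successfully on such degenerate inputs.
* All reports are timestamp-free and serialized with sorted keys, so
  identical runs are byte-identical — determinism is part of the output
  contract, not just an implementation detail.
* UTF-8 everywhere; molecule names with super/subscripts are stored as
  plain ASCII ("HCO3-", "Ca2+").

## Known limitations

* Betweenness and closeness are unweighted (hop counts); interaction
  confidence or sign is never used as an edge weight.
* The bottleneck score depends on the shortest-path-tree tie-breaking rule;
  other deterministic rules can give different scores on graphs with many
  equal-length paths.  The rule used here is documented above and shared by
  the test oracle.
* The hub rule μ + σ is scale-sensitive on very small networks, where one
  node can move the threshold appreciably.
* MCL cluster membership for nodes pulled equally by several systems is
  resolved lexicographically — stable, but an arbitrary convention.
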