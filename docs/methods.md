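# Methods

`ppinet` implements the network side of a biomarker follow-up study: given
a list of seed proteins (for the shipped fixtures, blood biomarkers of
post-stroke mortality) and a scored protein–protein interaction table, it
builds the analysis network, characterizes its topology, partitions it into
communities, finds the nodes that bridge communities, extracts dense
complexes, and tests node lists for gene-set over-representation.  This
note records the models, the parameters that matter, and the design choices
made where conventions differ between tools.

## Network construction

The background is an undirected simple graph with a per-edge confidence in
[0, 1].  STRING-style exports (integer combined scores 0–1000) are divided
by 1000 on input; duplicate unordered pairs keep the maximum confidence
(exports are deduplicated upstream, and maximum is the conservative merge);
self-loops are dropped.  Identifiers are uppercased and stripped, with
optional aliasing through an explicit table — the shipped stroke fixture
maps the fibrinogen protein label FBG to the gene symbol FGB, which is why
the 15-protein and 10-gene fixtures union to 24 seeds.

Confidence filtering keeps edges with confidence ≥ τ (default τ = 0.400,
read as a *minimum required* score, hence inclusive).  The zero-order
network is the induced subgraph on the seeds; the first-order network adds
a fixed budget k (default 50) of non-seed interactors.  Because the
upstream tools do not document their shell-selection rule, interactors are
ranked by a deterministic total order: number of distinct seed neighbors
(descending), then summed confidence over seed-incident edges (descending),
then identifier.  Seeds missing from the background are kept as isolated
nodes so seed bookkeeping never silently shrinks — real seed sets do
contain singletons.

## Topology and backbone

Statistics follow the Cytoscape Network Analyzer conventions: average
degree 2m/n; density 2m/(n(n−1)); average local clustering over *all*
nodes with degree < 2 contributing 0; diameter, radius and characteristic
path length on the largest connected component (finite values are reported
even when singletons exist); heterogeneity as the coefficient of variation
of the degree distribution with *population* variance.  Betweenness is
shortest-path betweenness with even splitting over equal-length paths,
normalized by (n−1)(n−2)/2 so a star center scores exactly 1 — this
normalization matches the magnitude of bottleneck values reported by the
desktop tools on networks of this size.  The backbone is the top `n_hubs`
nodes by degree (ties: betweenness, then identifier) plus the top
`n_bottlenecks` by betweenness among the remaining nodes; defaults 6 and 2.

Edge-count enrichment uses a binomial null: every node pair is an edge
independently with a user-supplied background density, and the p-value is
the exact upper tail P(X ≥ observed), floored at 1e-16 to mirror the usual
reporting convention.  Database nulls condition on node degrees and cannot
be reproduced without the database; the binomial null is a deliberate,
labelled approximation, and the reported "expected edges" is C(n, 2) times
the background density.

## Markov clustering

MCL iterates expansion (matrix squaring of a column-stochastic transition
matrix) and inflation (entrywise power r followed by column
renormalization), pruning entries below 1e-5 after each inflation (the
per-column maximum is never pruned), until the largest entry change falls
below 1e-8 or 200 iterations pass.  Self-loops are set to each node's
maximum incident confidence (1.0 for isolated nodes), which keeps the
transition matrix well-conditioned; a unit-loop policy is also available.

The limit matrix is read out through its attractors (nodes retaining
diagonal mass): attractor systems are the connected components among
attractors, and every other node joins the system receiving the largest
share of its column mass, with ties going to the system containing the
smallest identifier.  This resolution matters: a node attracted
symmetrically to two systems (the classical overlapping-membership case)
would otherwise spuriously merge them.  Cluster ids are numbered 1..k by
descending size, then smallest member.

Inflation controls granularity, and on sparse planted-partition graphs the
effect is strong.  On the synthetic benchmark below (blocks of 20 at
intra-block edge probability 0.3), inflation 1.7 typically returns the two
planted blocks (median adjusted Rand index 1.0 over 20 generator seeds),
inflation 2 returns ~5 clusters, and inflation 3 fragments each block into
micro-clusters of attractor size (median ARI 0.09).  The 2-community
results that motivate the default inflation of 3 come from far denser
networks (density ≈ 0.39 with dominant hubs); users clustering sparser
graphs should lower the inflation.  This granularity behavior was
confirmed against an independent minimal MCL implementation and is a
property of the algorithm, not of this implementation.

## Switch detection

A switch between two clusters is a node with many high-confidence links to
the *seed* members of both.  For each node, links with confidence strictly
above τ (default 0.4; strict, unlike the inclusive build threshold — both
conventions are preserved as the source tools state them) to seeds of
cluster A and of cluster B are counted, excluding the node itself; the
switch score is min(count_A, count_B), the only reading under which a
switch needs connections *in both* clusters.  Raw per-cluster counts are
reported so alternative scores can be recomputed, and the same counts at
the 0.7 and 0.9 confidence tiers are emitted as supplementary columns.
Ranking is by score, then total connections, then identifier.  All nodes
are scored; callers interested only in seed switches can filter the rows.

## MCODE complexes

Vertex weighting, complex prediction, and post-processing follow the
published Molecular Complex Detection algorithm, on topology only (edge
confidences are ignored).  A node's weight is k × density of the highest
k-core of its closed neighborhood (the node plus its neighbors).  Complex
prediction seeds at the highest-weight unvisited node and breadth-first
includes unvisited neighbors whose weight is within the vertex weight
percentage (vwp, default 0.2) of the seed weight; included nodes are
marked visited, so complexes are node-disjoint.  Haircut (default on)
iteratively removes members with fewer than two intra-complex connections;
fluff (default off) adds boundary neighbors whose closed-neighborhood
density exceeds `fluff_density`.  Complexes below `min_complex_size`
(default 3) are dropped; the rest are scored density × size and ranked
descending, matching the Metascape defaults.

## Over-representation analysis

The statistic is the accumulative hypergeometric tail
P(X ≥ k | N, K, n) computed with exact log-binomials and log-sum-exp,
where N is the annotation universe, K the term size, n the effective query
(unique, in-universe genes), and k the overlap.  The universe size is a
*mandatory explicit input* — the web tools this mirrors use hidden,
collection-specific universes, and silently defaulting one would make
p-values irreproducible.  When universe membership is known (synthetic
collections list it), query genes outside it are dropped with a warning;
when only the size is declared, all query genes are assumed in-universe.
Benjamini–Hochberg FDR is adjusted over exactly the rows emitted for one
collection (the per-table convention of the source reports), which makes
the effective family small when few terms pass the overlap filter
(`min_overlap`, default 3).  Each row carries ratio K/N, fold enrichment
(k/n)/(K/N), and strength log10(fold).

Redundant terms are grouped by Cohen's kappa between their binary
membership vectors over the query, single linkage at κ ≥ 0.3 by default;
each cluster is represented by its lowest-p member.  When chance agreement
is 1 (both vectors constant), kappa is defined as 1 for identical vectors
and 0 otherwise.  Single linkage on kappa is a stand-in for the source
tools' undocumented tree construction.

## Synthetic benchmark

The generator emulates the structure the analysis assumes: two
planted-partition blocks (defaults: 20 + 20 nodes, intra-block edge
probability 0.30, inter-block 0.02), intra-block confidences uniform on
(0.60, 0.99) and inter-block on (0.40, 0.70) so that the 0.4/0.7/0.9
confidence tiers are all exercised; 10 designated seeds per block; and 2
bridge nodes wired to exactly 3 seeds in each block at confidence ≥ 0.7 —
the ground-truth "switches".  Gene-set collections plant terms drawing
ceil(purity × size) members from block 1 (defaults: 3 terms of size 25 at
purity 0.8) among uniform decoys (default 50) in a universe of 5000
identifiers.  Everything is reproducible from a single integer seed.

What the generator does *not* emulate: the empirical STRING score
distribution, hub-dominated degree profiles, or correlated annotation
structure.  Passing recovery tests therefore demonstrates correctness of
the algorithms under the planted model, not performance on real
interactomes.  Measured over 20 generator seeds at the defaults: switch
detection recovers exactly the planted bridges in 19/20 runs (given the
true partition), ORA recovers all planted terms at FDR < 0.05 in 20/20
runs with zero decoy contamination, and MCL block recovery depends on
inflation as described above.

## Problem sizes and runtime

All test and acceptance computations run in seconds on one CPU: oracle
cross-checks use 50 random graphs of up to 12 nodes (topology and
betweenness against literal path enumeration), the full hypergeometric
configuration sweep up to N = 25 against integer draw counting, and the
recovery benchmark uses 20 generator seeds of ~42-node networks.  These
sizes were chosen because the oracles are exponential-cost enumerations;
the library itself comfortably handles networks orders of magnitude
larger.

## Known limitations

- The binomial edge null understates the significance structure of
  degree-conditioned database nulls; its p-values are comparable across
  runs of this package but not to database-reported ones.
- First-shell interactor ranking is this package's own deterministic rule;
  other tools' shells will differ in composition even at identical k.
- MCL at high inflation over-fragments sparse graphs (see above); the
  default inflation 3 is appropriate for dense seed-expanded networks.
- Kappa term clustering uses single linkage, which chains; at low
  thresholds clusters can be loose.
- The pipeline treats GMT collections as opaque inputs; no identifier
  mapping across namespaces is attempted beyond uppercasing and the
  explicit alias table.
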