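# Methods

## Scope and data model

`ppiscreen` implements the screening cascade that turns two lists of
differentially expressed proteins (136 up- and 139 down-regulated, shipped
as fixtures) into a small biomarker candidate panel. All stages operate on
a simple undirected graph over gene-symbol strings. Symbols are compared
by case-sensitive literal equality and no alias resolution is attempted:
the shipped tables mix gene symbols with protein accessions (e.g. SFN and
its accession P31947 both appear), and the published candidate counts are
only reproducible when such pairs are treated as distinct strings.

Self-loops are removed and parallel edges collapsed on input; degree,
betweenness and MCODE are all defined on the resulting simple graph.

## Network construction

A seed list is expanded against an interactome by one round of first
neighbors (`hops` is configurable; 1 is the default and the conventional
choice). The result is the *induced* subgraph on seeds plus neighbors, so
neighbor–neighbor edges are retained. Whether published networks of this
kind keep those edges is generally not stated; the induced-subgraph
convention is the deliberate, documented choice here because it makes the
output independent of traversal order and preserves the local topology
that module detection relies on. Seeds absent from the interactome are
logged and skipped; only a fully absent seed list is an error.

## Centrality

Degree is the count of incident edges. Betweenness centrality is computed
with Brandes' single-sweep accumulation algorithm (via networkx) and
reported normalized by `2/((n−1)(n−2))`, which maps it to [0, 1]; graphs
with fewer than 3 nodes get all zeros. On disconnected graphs the pair
sums run over reachable pairs while the normalization stays global — the
standard behavior of the algorithm. Published per-node BC values of 1.0
for internal nodes of large networks cannot arise under this
normalization (they indicate some per-component renormalization in the
original tool); such values are therefore not reproduced numerically, and
the fixtures are used only for the *ranking* they imply. Rank tables
assign ranks 1..n by value descending with ties broken by symbol
ascending, so every downstream selection is deterministic.

## MCODE

The canonical three-stage procedure is implemented from scratch:

* **Vertex weighting.** `w(v) = k_max · density(C_v)` where `C_v` is the
  highest k-core of the closed neighborhood of `v` and
  `density = 2E/(n(n−1))`; vertices with degree < `degree_cutoff`
  (default 2) get weight 0.
* **Prediction.** Complexes are seeded from the highest-weight unexamined
  vertex and grown breadth-first, admitting a neighbor when its weight
  exceeds `w_seed · (1 − node_score_cutoff)` (default cutoff 0.2), to a
  depth of at most `max_depth` (default 100). Examined vertices are never
  revisited, making complexes vertex-disjoint.
* **Post-processing.** Complexes without a 2-core (`k_core` default 2)
  are discarded; *haircut* (default on) iteratively removes members with
  fewer than two intra-complex edges; *fluff* (default off, threshold
  0.1) may add boundary neighbors, which are allowed to be shared.

Module score is density × member count. The retention filter keeps
modules with score strictly > 3 and strictly more than 6 nodes. Published
module tables of the kind shipped here sometimes report scores that are
inconsistent with density × size (e.g. a 65-node, 358-edge module scored
7.6 where density × size gives ≈ 11.2, suggesting a loop-degree density
variant); those printed scores are treated as informational fixture data,
never as values this implementation must reproduce.

All seed selection, expansion and output orders are tie-broken by symbol,
so repeated runs are identical.

## Screening cascade

Hubs are the top-`top_k` (default 20) symbols by degree rank, bottlenecks
the top-`top_k` by BC rank; hub-bottlenecks are their literal
intersection. Module residency intersects the hub-bottlenecks with the
union of module member sets. The panel keeps candidates with degree ≥
`degree_panel_cutoff` (default 1200). The cutoff is *inclusive*: in the
fixture tables a candidate at exactly 1208 is retained while 1158 is
dropped, which both strict and inclusive readings satisfy; inclusive is
chosen and documented. The cascade is monotone by construction
(`panel ⊆ module_resident ⊆ hub_bottlenecks ⊆ hubs ∪ bottlenecks`) and
asserted on every run.

**Module-residency fixture.** The shipped module table records, per
module, both the full printed hub list and the subset designated as
hub-bottleneck residents in the original table. The two disagree for
exactly one protein: ACTR2 is a hub-bottleneck by the centrality tables
and appears in a module's hub list, but the source table does not mark it
as a resident, and its summary count (12 proteins in 8 modules) excludes
it. `screen_printed_tables` follows the printed designation, reproducing
the 12; the literal hub-list intersection (13, including ACTR2) is
exercised and documented in the test suite. General-purpose code
(`filter_by_module_membership`) always performs the literal intersection.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
`P[X ≥ overlap]` for `X ~ Hypergeom(universe, term, module)` — the
right-tail Fisher exact convention of annotation tools. Multiplicity is
corrected per module, across the terms that module actually overlaps,
with the Holm step-down procedure (`p_(i) ← max_{j≤i} min(1,
(m−j+1)·p_(j))`); correcting per module rather than jointly across
modules matches how per-module top-term tables are reported. Terms are
grouped by Cohen's κ of their membership indicator vectors restricted to
the module's genes, with single-linkage components at κ ≥ 0.4
(group id = position of the component's lexicographically smallest term);
iterative group-merging heuristics of GUI tools are out of scope. κ is
1.0 for identical vectors and 0.0 when chance agreement is exactly 1.
Results are sorted by corrected p (ties by term id) and the top 3
returned by default.

## Synthetic data generator

The generator produces study instances with the structure the pipeline
assumes, so every stage is testable offline:

* **Backbone** — a Barabási–Albert preferential-attachment graph
  (default 2000 nodes, `attach_m = 2`), the simplest model with the
  hub-dominated, right-skewed degree distribution the screening stage
  relies on. No attempt is made to fit any actual interactome release.
* **Planted modules** — by default 3 disjoint random sets of 10 nodes,
  each topped up with random internal edges to density 0.9. Backbone
  edges running *between* two planted modules are removed so the planted
  ground truth is edge-separated: a single random bridge would make two
  near-cliques one dense region, and "the planted module" would no longer
  be a well-defined detection target. Modules keep all their edges into
  the rest of the backbone.
* **Seeds** — 140 nodes by default: one guaranteed member per planted
  module, the rest uniform without replacement.
* **Annotations** — 50 terms by default: one enriched term per planted
  module containing 90% of its members (`enriched_fraction = 0.9`) plus
  an equal number of background genes, the rest uniform random sets of
  10–50 genes over the whole node universe. The catalog sizes are chosen
  as a realistic miniature of a biological-process catalog restricted to
  a network of this order.

Node sizes, seed count, module count/size/density are the study
conditions the tests run under; `n_terms` and `enriched_fraction` are the
package's own defaults, fixed once as above. Every output is
deterministic given `rng_seed`, with independent substreams per stage.

What the generator does **not** emulate: real interactome degree-mixing
and clustering profiles, annotation term hierarchy and overlap structure,
literature/ascertainment bias toward well-studied proteins, or noisy
(false-positive) interactions. Passing the recovery and enrichment tests
therefore shows the algorithms are implemented correctly and behave as
designed on networks with the assumed statistics — not that the biology
of any particular disease panel is validated.

## Numerical and degenerate-input choices

* Ranks, BFS orders, complex ordering and group ids are all tie-broken by
  symbol; repeated runs are bitwise-identical.
* Betweenness is validated against exhaustive geodesic enumeration to
  1e−9 on graphs up to 12 nodes; the hypergeometric tail against
  combinatorial enumeration to 1e−12 for universes up to 25.
* Empty gene lists, empty annotation terms, duplicate term ids, seed
  lists entirely absent from the interactome, and panel candidates
  without a degree entry are hard errors; duplicate gene symbols and
  seeds missing from the interactome are warnings.
* Density of a single-node (sub)graph is defined as 0, so isolated
  vertices never score.

## Problem sizes

The test suite and the acceptance script run on 2000-node synthetic
interactomes (the defaults above), 200 random ≤ 12-node graphs for the
betweenness oracle, 5 generator seeds for module recovery, and the full
packaged fixture tables; a complete run of suite plus acceptance script
takes on the order of a minute on one CPU.

## Known limitations

* The original networks (7312 and 6707 nodes) cannot be reconstructed:
  the interactome database and version behind them are not identified, so
  network-dependent numbers (module scores and sizes, specific GO terms)
  are out of reach by design; only counts computable from the printed
  tables are reproduced exactly.
* One-hop expansion is an assumption (made explicit and configurable);
  the original construction rule is unstated.
* Kappa grouping is single-linkage at a fixed threshold, deliberately
  simpler than iterative GUI grouping heuristics.
* The MCODE fluff option is implemented but off by default and not part
  of the replicated cascade.
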