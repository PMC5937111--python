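# ppiscreen

Hub–bottleneck screening of protein–protein interaction (PPI) networks:
a tested, reusable implementation of the network-biology cascade used to
narrow lists of differentially expressed proteins down to small biomarker
candidate panels.

## The problem and the method

Proteome-profiling studies of a disease tissue typically yield a few
hundred differentially expressed proteins — far too many to act on. A
standard systems-biology strategy ranks them by their position in the PPI
network instead:

1. **Network construction.** The up- and down-regulated protein lists are
   submitted to an interactome and expanded by first neighbors, giving one
   induced subgraph per direction.
2. **Centrality.** For every node, degree `deg(v)` and betweenness
   centrality `BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st` (Brandes' algorithm,
   normalized by `2/((n−1)(n−2))`) are computed. The top-20 by degree are
   **hubs**, the top-20 by BC are **bottlenecks**, and their intersection
   — the **hub-bottlenecks** — are the key-protein candidates.
3. **Module detection.** MCODE finds dense complexes: vertices are
   weighted by the core-clustering coefficient (density of the highest
   k-core of the closed neighborhood, times its k), complexes grow
   greedily from the heaviest vertex admitting neighbors with weight
   `> w_seed·(1 − node_score_cutoff)`, and are post-processed (2-core
   check, haircut). Module score = density × size; modules with
   score > 3 and > 6 nodes are retained.
4. **Enrichment.** Each retained module is tested for annotation
   over-representation with a one-sided hypergeometric test, corrected by
   the Holm ("Bonferroni step down") procedure; redundant terms are
   grouped by Cohen's κ ≥ 0.4.
5. **Panel selection.** Hub-bottlenecks that reside in a retained module
   and pass a degree cutoff (≥ 1200) form the final biomarker panel.

The package ships the printed screening tables of a human
laryngeal-cancer proteome study as plain-text fixtures, so the published
cascade can be replayed end to end, and a synthetic-interactome generator
(scale-free backbone, planted dense modules, planted-enrichment
annotation catalogs) so every stage is testable without any database
download.

## Worked example

```sh
python examples/replay_published_screen.py
```

prints

```
differentially expressed proteins: 136 up, 139 down, 275 total
hub-bottlenecks: 15 up + 11 down = 26
module-resident hub-bottlenecks: 12
  ['ACTG1', 'CALM3', 'CAND1', 'DYNLL1', 'FUS', 'HNRNPA1', 'HNRNPD', 'HSP90AA1', 'KPNB1', 'PPP2R1A', 'XRCC5', 'YWHAZ']
biomarker panel (degree >= 1200): ['CALM3', 'HSP90AA1', 'PPP2R1A', 'YWHAZ']
```

Reading: of the 275 differentially expressed proteins, 26 are both among
the top-20 most connected (hubs) and the top-20 most path-central
(bottlenecks) of their network; 12 of those additionally sit inside a
dense network module; and 4 of the 12 — YWHAZ and PPP2R1A (up-regulated),
HSP90AA1 and CALM3 (down-regulated) — clear the degree ≥ 1200 cutoff and
form the candidate panel.

`examples/synthetic_pipeline.py` runs the same cascade on a generated
2000-node interactome with three planted dense modules and shows each
planted module being recovered (Jaccard ≥ 0.8) with its planted
annotation term ranked first.

A thin CLI mirrors the stages (`ppiscreen synth | centrality | mcode |
screen | enrich`); see `ppiscreen --help`.

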