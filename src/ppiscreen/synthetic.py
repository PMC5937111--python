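"""Synthetic interactomes with planted dense modules and enriched terms.

The generator emulates the statistical structure the screening pipeline
assumes of a real interactome: a scale-free (preferential-attachment)
backbone whose degree distribution is dominated by hubs, a handful of
planted near-clique modules dense enough for complex detection to find,
a seed list emulating a differentially-expressed protein panel, and an
annotation catalog in which each planted module has one genuinely
enriched term among random background terms.

Everything is deterministic given ``rng_seed``; independent substreams
are derived for the backbone, module planting, seed drawing and
annotation sampling so the stages do not perturb each other.

Node labels are synthetic symbols ``G000001``... so fixture networks stay
disjoint from real gene namespaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import AnnotationCatalog, InteractionNetwork

__all__ = [
    "SyntheticSpec",
    "generate_interactome",
    "planted_modules",
    "draw_seed_list",
    "generate_annotations",
    "planted_term_id",
]

_PLANTED_KEY = "planted_modules"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study instance.

    Defaults describe the study conditions the pipeline is exercised
    under: a 2000-node scale-free backbone (2 attachment edges per new
    node), 140 seed proteins, and 3 planted 10-node modules of internal
    density 0.9 annotated by one enriched term each inside a 50-term
    catalog.
    """

    n_nodes: int = 2000
    attach_m: int = 2
    n_seeds: int = 140
    n_planted_modules: int = 3
    planted_size: int = 10
    planted_density: float = 0.9
    n_terms: int = 50
    enriched_fraction: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.attach_m < 1 or self.n_seeds < 1:
            raise ValueError("n_nodes, attach_m and n_seeds must be positive")
        if self.attach_m >= self.n_nodes:
            raise ValueError("attach_m must be smaller than n_nodes")
        if self.n_seeds > self.n_nodes:
            raise ValueError("n_seeds cannot exceed n_nodes")
        if self.n_planted_modules < 0:
            raise ValueError("n_planted_modules must be non-negative")
        if self.n_planted_modules > 0:
            if self.planted_size < 4:
                raise ValueError("planted_size must be >= 4")
            if self.planted_size * self.n_planted_modules > self.n_nodes:
                raise ValueError("planted modules do not fit into the network")
            if not 0.5 < self.planted_density <= 1.0:
                raise ValueError("planted_density must lie in (0.5, 1.0]")
            if self.n_seeds < self.n_planted_modules:
                raise ValueError("need at least one seed per planted module")
        if self.n_terms < max(1, self.n_planted_modules):
            raise ValueError("n_terms must cover every planted module")
        if not 0.0 < self.enriched_fraction <= 1.0:
            raise ValueError("enriched_fraction must lie in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream for one generation stage."""
        return np.random.default_rng([self.rng_seed, stream])


def _label(i: int) -> str:
    return f"G{i + 1:06d}"


def generate_interactome(spec: SyntheticSpec) -> InteractionNetwork:
    """Scale-free backbone plus planted dense modules.

    The backbone is a Barabasi-Albert graph with ``attach_m`` edges per
    arriving node.  Each planted module is a disjoint random subset of
    ``planted_size`` nodes whose induced subgraph is topped up with
    random internal edges until its density reaches
    ``planted_density``.  Backbone edges that happen to run between two
    different planted modules are removed, so the planted structures are
    edge-disjoint and the ground truth is well separated (modules keep
    their edges into the rest of the backbone).  The planted member sets
    are stored on the graph (see :func:`planted_modules`).
    """
    backbone_rng = spec.rng(0)
    g = nx.barabasi_albert_graph(
        spec.n_nodes, spec.attach_m,
        seed=int(backbone_rng.integers(0, 2**31 - 1)),
    )
    g = nx.relabel_nodes(g, {i: _label(i) for i in g.nodes})

    plant_rng = spec.rng(1)
    labels = sorted(g.nodes)
    chosen = plant_rng.choice(
        len(labels),
        size=spec.planted_size * spec.n_planted_modules,
        replace=False,
    )
    member_sets = [
        sorted(
            labels[i]
            for i in chosen[m * spec.planted_size : (m + 1) * spec.planted_size]
        )
        for m in range(spec.n_planted_modules)
    ]
    # separate the ground truth: drop backbone edges bridging two modules
    owner = {
        v: m for m, members in enumerate(member_sets) for v in members
    }
    g.remove_edges_from(
        [
            (u, v)
            for u, v in list(g.edges)
            if u in owner and v in owner and owner[u] != owner[v]
        ]
    )
    modules: list[frozenset[str]] = []
    for members in member_sets:
        k = len(members)
        target = math.ceil(spec.planted_density * k * (k - 1) / 2)
        if target > k * (k - 1) // 2:
            raise ValueError(
                "planted_density unreachable without multi-edges"
            )
        missing = [
            (members[i], members[j])
            for i in range(k)
            for j in range(i + 1, k)
            if not g.has_edge(members[i], members[j])
        ]
        have = k * (k - 1) // 2 - len(missing)
        need = target - have
        if need > 0:
            pick = plant_rng.choice(len(missing), size=need, replace=False)
            g.add_edges_from(missing[i] for i in sorted(pick))
        modules.append(frozenset(members))
    g.graph[_PLANTED_KEY] = modules
    return InteractionNetwork(g, {n: False for n in g.nodes})


def planted_modules(network: InteractionNetwork) -> list[frozenset[str]]:
    """The planted member sets recorded by :func:`generate_interactome`."""
    return list(network.graph.graph.get(_PLANTED_KEY, []))


def draw_seed_list(network: InteractionNetwork, spec: SyntheticSpec) -> set[str]:
    """Sample ``n_seeds`` nodes, guaranteeing one per planted module.

    One member of every planted module is drawn first, then the
    remainder is a uniform sample without replacement from the remaining
    nodes.  Deterministic given ``rng_seed``.
    """
    rng = spec.rng(2)
    nodes = sorted(network.graph.nodes)
    if spec.n_seeds > len(nodes):
        raise ValueError("n_seeds exceeds the network size")
    seeds: set[str] = set()
    for members in planted_modules(network):
        ordered = sorted(members)
        seeds.add(ordered[int(rng.integers(0, len(ordered)))])
    rest = [n for n in nodes if n not in seeds]
    extra = spec.n_seeds - len(seeds)
    if extra > 0:
        pick = rng.choice(len(rest), size=extra, replace=False)
        seeds.update(rest[i] for i in pick)
    return seeds


def planted_term_id(module_index: int) -> str:
    """Term id of the enriched annotation for planted module i (0-based)."""
    return f"PT{module_index + 1:03d}"


def generate_annotations(
    network: InteractionNetwork, spec: SyntheticSpec
) -> AnnotationCatalog:
    """Annotation catalog with one enriched term per planted module.

    The enriched term for module i (id ``PT00{i+1}``) contains
    ``enriched_fraction`` of that module's members plus an equal number
    of random background genes; the remaining terms are uniform random
    gene sets of 10-50 genes.  Universe = all network nodes.
    """
    rng = spec.rng(3)
    nodes = sorted(network.graph.nodes)
    universe = frozenset(nodes)
    terms: dict[str, tuple[str, frozenset[str]]] = {}

    planted = planted_modules(network)
    for i, members in enumerate(planted):
        ordered = sorted(members)
        n_in = max(1, round(spec.enriched_fraction * len(ordered)))
        inside = [ordered[j] for j in rng.choice(len(ordered), size=n_in, replace=False)]
        background_pool = [n for n in nodes if n not in members]
        outside = [
            background_pool[j]
            for j in rng.choice(len(background_pool), size=len(ordered), replace=False)
        ]
        terms[planted_term_id(i)] = (
            f"planted enrichment for module {i + 1}",
            frozenset(inside) | frozenset(outside),
        )

    for j in range(spec.n_terms - len(planted)):
        size = int(rng.integers(10, 51))
        size = min(size, len(nodes))
        members = frozenset(
            nodes[k] for k in rng.choice(len(nodes), size=size, replace=False)
        )
        terms[f"RT{j + 1:03d}"] = ("random background set", members)

    return AnnotationCatalog(terms, universe)
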