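"""Molecular Complex Detection (MCODE) with deterministic tie-breaking.

The algorithm finds locally dense regions ("complexes" or modules) of a
simple undirected graph in three stages:

1. **Vertex weighting.**  Each vertex is scored by its core-clustering
   coefficient: the density of the highest k-core of its closed
   neighborhood, multiplied by that core's k.  Vertices whose degree is
   below ``degree_cutoff`` get weight 0.
2. **Complex prediction.**  Starting from the highest-weighted unseen
   vertex, a complex grows outward breadth-first, admitting a neighbor
   whenever its weight exceeds ``seed_weight * (1 - node_score_cutoff)``.
   Vertices already claimed by an earlier complex are never revisited, so
   complexes are vertex-disjoint (before optional fluffing).
3. **Post-processing.**  Complexes lacking a ``k_core``-core are
   discarded; *haircut* iteratively strips members with fewer than two
   intra-complex edges; *fluff* optionally adds boundary neighbors whose
   closed-neighborhood density exceeds ``fluff_density`` (fluffed nodes
   may be shared between complexes).

A complex's score is its density times its size, density being
2E/(n(n-1)).  All iteration orders are tie-broken by symbol so output is
reproducible for a fixed input.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .model import InteractionNetwork

__all__ = [
    "McodeParams",
    "NetworkModule",
    "vertex_weights",
    "predict_complexes",
    "filter_modules",
]


@dataclass(frozen=True)
class McodeParams:
    """MCODE tuning parameters (defaults = the study's stated values)."""

    node_score_cutoff: float = 0.2
    k_core: int = 2
    degree_cutoff: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff < 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1)")
        if self.k_core < 1 or self.degree_cutoff < 0 or self.max_depth < 1:
            raise ValueError("k_core/degree_cutoff/max_depth out of range")


@dataclass(frozen=True)
class NetworkModule:
    """One detected complex: member set, seed vertex and score."""

    members: frozenset[str]
    seed: str
    score: float
    n_nodes: int
    n_edges: int

    def jaccard(self, other: Iterable[str]) -> float:
        other = set(other)
        union = self.members | other
        return len(self.members & other) / len(union) if union else 1.0


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def _module_from(graph: nx.Graph, members: set[str], seed: str) -> NetworkModule:
    sub = graph.subgraph(members)
    n, e = sub.number_of_nodes(), sub.number_of_edges()
    return NetworkModule(
        members=frozenset(members),
        seed=seed,
        score=_density(n, e) * n,
        n_nodes=n,
        n_edges=e,
    )


def vertex_weights(
    network: InteractionNetwork, params: McodeParams = McodeParams()
) -> dict[str, float]:
    """Core-clustering-coefficient weights for every vertex.

    weight(v) = k_max * density(highest k-core of the closed neighborhood
    of v), or 0 when deg(v) < ``degree_cutoff``.
    """
    g = network.graph
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = set(g.neighbors(v)) | {v}
        sub = g.subgraph(closed)
        core_num = nx.core_number(sub)
        k_max = max(core_num.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, k in core_num.items() if k >= k_max]
        core = sub.subgraph(core_nodes)
        weights[v] = k_max * _density(core.number_of_nodes(), core.number_of_edges())
    return weights


def _expand(
    g: nx.Graph,
    seed: str,
    weights: dict[str, float],
    claimed: set[str],
    params: McodeParams,
) -> set[str]:
    """Breadth-first expansion from ``seed`` under the weight threshold."""
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    queue: deque[tuple[str, int]] = deque([(seed, 0)])
    while queue:
        v, depth = queue.popleft()
        if depth >= params.max_depth:
            continue
        for u in sorted(g.neighbors(v)):
            if u in members or u in claimed:
                continue
            if weights[u] > threshold:
                members.add(u)
                queue.append((u, depth + 1))
    return members


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively drop members with < 2 intra-complex edges (the 2-core)."""
    members = set(members)
    while True:
        sub = g.subgraph(members)
        weak = {v for v in members if sub.degree(v) < 2}
        if not weak:
            return members
        members -= weak


def _fluff(g: nx.Graph, members: set[str], params: McodeParams) -> set[str]:
    """Add boundary neighbors whose closed-neighborhood density is high."""
    added = set()
    for v in sorted(members):
        for u in sorted(g.neighbors(v)):
            if u in members or u in added:
                continue
            closed = set(g.neighbors(u)) | {u}
            sub = g.subgraph(closed)
            if _density(sub.number_of_nodes(), sub.number_of_edges()) > params.fluff_density:
                added.add(u)
    return members | added


def predict_complexes(
    network: InteractionNetwork, params: McodeParams = McodeParams()
) -> list[NetworkModule]:
    """Run the full MCODE procedure and return scored complexes.

    Complexes are returned sorted by score descending, ties by member
    count descending then seed symbol ascending.
    """
    g = network.graph
    weights = vertex_weights(network, params)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    claimed: set[str] = set()
    modules: list[NetworkModule] = []
    for seed in order:
        if seed in claimed or weights[seed] <= 0.0:
            continue
        raw = _expand(g, seed, weights, claimed, params)
        claimed |= raw  # examined vertices are never revisited
        core = nx.k_core(g.subgraph(raw), k=params.k_core)
        if core.number_of_nodes() == 0:
            continue
        members = set(raw)
        if params.haircut:
            members = _haircut(g, members)
        if params.fluff:
            members = _fluff(g, members, params)
        if not members:
            continue
        mod_seed = seed if seed in members else min(members)
        modules.append(_module_from(g, members, mod_seed))
    modules.sort(key=lambda m: (-m.score, -m.n_nodes, m.seed))
    return modules


def filter_modules(
    modules: Iterable[NetworkModule],
    min_score: float = 3.0,
    min_nodes: int = 6,
) -> list[NetworkModule]:
    """Retain modules with score strictly > min_score and strictly more
    than min_nodes members (the study's retention rule)."""
    return [m for m in modules if m.score > min_score and m.n_nodes > min_nodes]
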