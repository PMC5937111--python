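"""Core record and graph types shared by all pipeline stages.

The pipeline operates on three kinds of objects: differentially expressed
gene records (symbol plus regulation direction), an undirected simple
interaction network whose nodes remember whether they entered as a seed
(a member of the differentially-expressed list) or as a recruited first
neighbor, and a catalog of annotation gene sets used for enrichment.

Gene symbols are compared by case-sensitive exact string equality
throughout; no alias or identifier mapping is performed. This is
deliberate: screening counts are only reproducible under literal matching
(e.g. SFN and P31947 denote the same protein but are distinct strings and
are treated as such).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "GeneRecord",
    "InteractionNetwork",
    "AnnotationCatalog",
    "expand_seed_neighborhood",
]


class Direction(str, Enum):
    """Regulation direction of a differentially expressed protein."""

    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class GeneRecord:
    """One differentially expressed protein.

    Parameters
    ----------
    symbol
        Gene symbol; non-empty and free of whitespace.
    direction
        Regulation direction relative to healthy control tissue.
    """

    symbol: str
    direction: Direction

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if any(c.isspace() for c in self.symbol):
            raise ValueError(f"gene symbol contains whitespace: {self.symbol!r}")


@dataclass
class InteractionNetwork:
    """Undirected simple graph over gene symbols with seed provenance.

    ``graph`` is a :class:`networkx.Graph`; self-loops and parallel edges
    are never present.  ``seed_flags`` maps every node to True when it was
    a member of the input differentially-expressed list and False when it
    was recruited as a first neighbor.
    """

    graph: nx.Graph
    seed_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)
        # every node gets a flag; flags for absent nodes are dropped
        self.seed_flags = {
            n: bool(self.seed_flags.get(n, False)) for n in self.graph.nodes
        }

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        seeds: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        seeds = set(seeds)
        return cls(g, {n: n in seeds for n in g.nodes})

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def seed_nodes(self) -> set[str]:
        return {n for n, f in self.seed_flags.items() if f}

    def is_seed(self, symbol: str) -> bool:
        return self.seed_flags.get(symbol, False)


@dataclass
class AnnotationCatalog:
    """Named gene sets (GO-style terms) plus the gene universe they live in.

    ``terms`` maps a term id to a ``(description, member set)`` pair.
    Every member of every term belongs to ``universe``; empty terms are
    rejected.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"annotation term {tid!r} has no members")
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"term {tid!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def description(self, term_id: str) -> str:
        return self.terms[term_id][0]


def expand_seed_neighborhood(
    seeds: Iterable[str],
    interactome: InteractionNetwork,
    hops: int = 1,
) -> InteractionNetwork:
    """Induce the interactome subgraph on seeds plus their neighbors.

    This is the conventional network-construction step: a list of
    differentially expressed proteins is submitted to an interactome and
    expanded by ``hops`` rounds of first neighbors (default one hop).  The
    result is the *induced* subgraph: every interactome edge between two
    retained nodes is kept, including neighbor-neighbor edges.

    Seeds absent from the interactome are logged and ignored; if no seed
    is present at all a :class:`ValueError` is raised.
    """
    if hops < 0:
        raise ValueError("hops must be non-negative")
    seeds = set(seeds)
    present = seeds & set(interactome.graph.nodes)
    absent = seeds - present
    if absent:
        logger.warning(
            "%d of %d seeds absent from interactome (e.g. %s)",
            len(absent), len(seeds), sorted(absent)[:5],
        )
    if not present:
        raise ValueError("no seed symbol is present in the interactome")
    keep = set(present)
    frontier = set(present)
    for _ in range(hops):
        frontier = {
            nbr for n in frontier for nbr in interactome.graph.neighbors(n)
        } - keep
        keep |= frontier
    sub = interactome.graph.subgraph(keep).copy()
    return InteractionNetwork(sub, {n: n in seeds for n in sub.nodes})
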