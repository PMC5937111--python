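"""The hub-bottleneck screening cascade.

The cascade narrows a centrality table down to a small biomarker panel:

1. hubs — the top-k nodes by degree (k = 20 by default),
2. bottlenecks — the top-k nodes by betweenness centrality,
3. hub-bottlenecks — their intersection,
4. module residents — hub-bottlenecks that sit inside a detected network
   module,
5. panel — module residents whose degree passes a cutoff (>= 1200 by
   default; the cutoff is inclusive).

Each stage only removes candidates, so panel ⊆ module_resident ⊆
hub_bottlenecks ⊆ hubs ∪ bottlenecks on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .centrality import CentralityTable
from .mcode import NetworkModule

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "ScreenResult",
    "select_hubs",
    "select_bottlenecks",
    "intersect_hub_bottleneck",
    "filter_by_module_membership",
    "select_panel",
    "run_cascade",
]


@dataclass(frozen=True)
class ScreenParams:
    """Cascade knobs; defaults are the study's stated values."""

    top_k: int = 20
    degree_panel_cutoff: float = 1200.0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class ScreenResult:
    """All intermediate candidate sets of one cascade run."""

    hubs: tuple[str, ...]
    bottlenecks: tuple[str, ...]
    hub_bottlenecks: frozenset[str]
    module_resident: frozenset[str]
    panel: frozenset[str]

    def __post_init__(self) -> None:
        assert self.hub_bottlenecks == set(self.hubs) & set(self.bottlenecks)
        assert self.module_resident <= self.hub_bottlenecks
        assert self.panel <= self.module_resident


def _top(table: CentralityTable, column: str, params: ScreenParams) -> list[str]:
    if len(table) == 0:
        raise ValueError("centrality table is empty")
    if len(table) < params.top_k:
        logger.warning(
            "table has only %d rows; top_k=%d returns all of them",
            len(table), params.top_k,
        )
    return table.top_by(column, params.top_k)


def select_hubs(
    table: CentralityTable, params: ScreenParams = ScreenParams()
) -> list[str]:
    """Top-k symbols by degree rank (ties already broken in the table)."""
    return _top(table, "degree", params)


def select_bottlenecks(
    table: CentralityTable, params: ScreenParams = ScreenParams()
) -> list[str]:
    """Top-k symbols by betweenness rank."""
    return _top(table, "bc", params)


def intersect_hub_bottleneck(
    hubs: Iterable[str], bottlenecks: Iterable[str]
) -> set[str]:
    """Nodes that are both hub and bottleneck (literal, case-sensitive)."""
    return set(hubs) & set(bottlenecks)


def filter_by_module_membership(
    hub_bottlenecks: Iterable[str], modules: Iterable[NetworkModule]
) -> set[str]:
    """Hub-bottlenecks that appear in at least one module's member set."""
    in_modules: set[str] = set()
    for m in modules:
        in_modules |= m.members
    return set(hub_bottlenecks) & in_modules


def select_panel(
    candidates: Iterable[str],
    degrees: Mapping[str, int],
    params: ScreenParams = ScreenParams(),
) -> set[str]:
    """Candidates whose degree passes the (inclusive) panel cutoff."""
    candidates = set(candidates)
    missing = sorted(c for c in candidates if c not in degrees)
    if missing:
        raise KeyError(f"no degree recorded for candidates: {missing[:5]}")
    return {c for c in candidates if degrees[c] >= params.degree_panel_cutoff}


def run_cascade(
    table: CentralityTable,
    modules: Iterable[NetworkModule],
    params: ScreenParams = ScreenParams(),
) -> ScreenResult:
    """Run all five stages on one network and return every candidate set."""
    hubs = select_hubs(table, params)
    bottlenecks = select_bottlenecks(table, params)
    hb = intersect_hub_bottleneck(hubs, bottlenecks)
    resident = filter_by_module_membership(hb, modules)
    panel = select_panel(resident, table.degree_map(), params)
    return ScreenResult(
        hubs=tuple(hubs),
        bottlenecks=tuple(bottlenecks),
        hub_bottlenecks=frozenset(hb),
        module_resident=frozenset(resident),
        panel=frozenset(panel),
    )
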