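"""Degree and betweenness centrality with deterministic ranking.

Hubs are defined by connectivity (degree) and bottlenecks by betweenness
centrality, the fraction of all-pairs geodesics passing through a node.
Betweenness is computed with the single-sweep accumulation algorithm of
Brandes (O(VE) on unweighted graphs, via networkx) and reported normalized
to [0, 1] by 2/((n-1)(n-2)), matching what network-analysis GUIs report.
On disconnected graphs pair sums run over reachable pairs only while the
normalization stays global, so values in small components shrink
accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .model import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["CentralityTable", "compute_degree", "compute_betweenness", "rank_table"]


def compute_degree(network: InteractionNetwork) -> dict[str, int]:
    """Number of incident edges per node; isolated nodes get 0."""
    return {n: int(d) for n, d in network.graph.degree()}


def compute_betweenness(
    network: InteractionNetwork, normalized: bool = True
) -> dict[str, float]:
    """Betweenness centrality BC(v) = sum over s!=v!=t of sigma_st(v)/sigma_st.

    With ``normalized`` the raw sum is scaled by 2/((n-1)(n-2)) for
    n >= 3; graphs with fewer than 3 nodes have no intermediate vertices
    and every value is 0.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in g.nodes}
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return {v: float(x) for v, x in bc.items()}


@dataclass
class CentralityTable:
    """Per-node degree and betweenness with deterministic ranks.

    ``rows`` has columns symbol, degree, bc, degree_rank, bc_rank and is
    sorted by degree_rank.  Ranks 1..n are assigned by value descending;
    ties are broken by symbol ascending so the table is reproducible.
    """

    rows: pd.DataFrame

    @classmethod
    def from_values(
        cls, degree: Mapping[str, int], bc: Mapping[str, float]
    ) -> "CentralityTable":
        symbols = sorted(set(degree) | set(bc))
        df = pd.DataFrame(
            {
                "symbol": symbols,
                "degree": [int(degree.get(s, 0)) for s in symbols],
                "bc": [float(bc.get(s, 0.0)) for s in symbols],
            }
        )
        for col in ("degree", "bc"):
            order = df.sort_values(
                [col, "symbol"], ascending=[False, True], kind="mergesort"
            ).index
            ranks = pd.Series(range(1, len(df) + 1), index=order)
            df[f"{col}_rank"] = ranks
        return cls(
            df.sort_values("degree_rank", kind="mergesort").reset_index(drop=True)
        )

    def top_by(self, column: str, k: int) -> list[str]:
        """First k symbols by ``column`` rank ('degree' or 'bc')."""
        ordered = self.rows.sort_values(f"{column}_rank", kind="mergesort")
        return ordered["symbol"].head(k).tolist()

    def degree_map(self) -> dict[str, int]:
        return dict(zip(self.rows["symbol"], self.rows["degree"]))

    def __len__(self) -> int:
        return len(self.rows)


def rank_table(network: InteractionNetwork) -> CentralityTable:
    """Compute degree and normalized betweenness and rank both."""
    return CentralityTable.from_values(
        compute_degree(network), compute_betweenness(network)
    )
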