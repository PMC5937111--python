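"""Loaders for the packaged printed screening tables.

The package ships, as plain TSV fixtures, the published screening tables
of a laryngeal-cancer proteome study: the 136 up- and 139 down-regulated
protein lists, the top-20 hub (degree) and top-20 bottleneck
(betweenness) tables of each network, and the per-module hub lists of the
detected network modules.  These anchor the regression tests and let the
full cascade be replayed without any interactome download.

Identifiers are kept exactly as printed — including protein accessions
such as P31947 (an alias of SFN) appearing alongside gene symbols — since
the published candidate counts are only reproducible under literal string
matching.

Note on module residency: the module table records both each module's
full printed hub list (``hubs``) and the subset designated as
hub-bottleneck module residents in the published table
(``hub_bottlenecks``).  The two differ for exactly one protein (ACTR2,
a hub-bottleneck by the centrality tables but not marked as a module
resident in the module table); :func:`screen_printed_tables` follows the
published designation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .centrality import CentralityTable
from .mcode import NetworkModule
from .model import Direction, GeneRecord
from .screening import (
    ScreenParams,
    ScreenResult,
    intersect_hub_bottleneck,
    select_bottlenecks,
    select_hubs,
    select_panel,
)

__all__ = [
    "fixture_path",
    "load_gene_records",
    "load_centrality_fixture",
    "load_module_fixture",
    "ModuleRow",
    "screen_printed_tables",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("ppiscreen") / "data" / name)


def load_gene_records(direction: Direction | str) -> list[GeneRecord]:
    """The printed differentially-expressed protein list for one direction."""
    from .io import read_gene_list

    direction = Direction(direction)
    name = "deg_up.tsv" if direction is Direction.UP else "deg_down.tsv"
    return read_gene_list(fixture_path(name), direction)


def load_centrality_fixture(network: str) -> CentralityTable:
    """Centrality table rebuilt from the printed top-20 degree/BC blocks.

    ``network`` is ``"up"`` or ``"down"``.  Symbols present in only one
    of the two blocks get 0 for the other quantity, which keeps them out
    of that quantity's top-20 — exactly the published selection.
    """
    deg = pd.read_csv(fixture_path("hub_degree.tsv"), sep="\t")
    bc = pd.read_csv(fixture_path("bottleneck_bc.tsv"), sep="\t")
    deg = deg[deg["network"] == network]
    bc = bc[bc["network"] == network]
    if deg.empty or bc.empty:
        raise ValueError(f"unknown network {network!r}; expected 'up' or 'down'")
    return CentralityTable.from_values(
        dict(zip(deg["symbol"], deg["degree"])),
        dict(zip(bc["symbol"], bc["bc"])),
    )


@dataclass(frozen=True)
class ModuleRow:
    """One printed module row: id, score, size and its hub lists."""

    network: str
    module_id: str
    score: float
    n_nodes: int
    n_edges: int
    seed: str | None
    hubs: frozenset[str]
    hub_bottlenecks: frozenset[str]


def _split(cell: str) -> frozenset[str]:
    cell = str(cell).strip()
    if cell in ("-", "", "nan"):
        return frozenset()
    return frozenset(s.strip() for s in cell.split(",") if s.strip())


def load_module_fixture(network: str | None = None) -> list[ModuleRow]:
    """The printed module table, optionally restricted to one network."""
    df = pd.read_csv(fixture_path("module_hubs.tsv"), sep="\t")
    if network is not None:
        df = df[df["network"] == network]
        if df.empty:
            raise ValueError(f"unknown network {network!r}")
    rows = []
    for r in df.itertuples(index=False):
        seed = None if str(r.seed) in ("-", "NS", "nan") else str(r.seed)
        rows.append(
            ModuleRow(
                network=r.network,
                module_id=r.module_id,
                score=float(r.score),
                n_nodes=int(r.n_nodes),
                n_edges=int(r.n_edges),
                seed=seed,
                hubs=_split(r.hubs),
                hub_bottlenecks=_split(r.hub_bottlenecks),
            )
        )
    return rows


def screen_printed_tables(
    params: ScreenParams = ScreenParams(),
) -> dict[str, object]:
    """Replay the published screening cascade from the printed tables.

    Runs hub and bottleneck selection per network, intersects them,
    filters by the module table's hub-bottleneck residency record, and
    applies the degree panel cutoff.  Returns a dict with per-network
    hub/bottleneck/hub-bottleneck sets and the combined module-resident
    set and biomarker panel.
    """
    out: dict[str, object] = {}
    hub_bottlenecks: dict[str, set[str]] = {}
    degrees: dict[str, int] = {}
    for network in ("up", "down"):
        table = load_centrality_fixture(network)
        hubs = select_hubs(table, params)
        bottlenecks = select_bottlenecks(table, params)
        hb = intersect_hub_bottleneck(hubs, bottlenecks)
        hub_bottlenecks[network] = hb
        degrees.update(table.degree_map())
        out[f"{network}_hubs"] = hubs
        out[f"{network}_bottlenecks"] = bottlenecks
        out[f"{network}_hub_bottlenecks"] = hb

    all_hb = hub_bottlenecks["up"] | hub_bottlenecks["down"]
    resident_record: set[str] = set()
    for row in load_module_fixture():
        resident_record |= row.hub_bottlenecks
    module_resident = all_hb & resident_record
    panel = select_panel(module_resident, degrees, params)

    out["hub_bottlenecks"] = all_hb
    out["module_resident"] = module_resident
    out["panel"] = panel
    return out
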