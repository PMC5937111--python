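"""Readers and writers for gene lists, edge lists, GMT gene sets and config.

Supported formats are all plain text:

* gene list — TSV, one symbol per row (extra columns ignored); a header
  row may be present and can be auto-detected,
* edge list — SIF (``node relation node ...``) or two-column TSV,
* annotation catalog — standard GMT (term, description, members...),
* pipeline configuration — YAML mapping with the screening defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import yaml

from .model import AnnotationCatalog, Direction, GeneRecord, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_list",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "PipelineConfig",
    "load_config",
]

_HEADER_WORDS = {"symbol", "gene", "gene_name", "id", "name"}


def read_gene_list(
    path: str | Path,
    direction: Direction | str,
    header: bool | Literal["auto"] = "auto",
) -> list[GeneRecord]:
    """Read a one-symbol-per-row TSV into deduplicated gene records.

    Order is preserved; duplicate symbols are dropped with a warning.
    An empty file, or a symbol containing internal whitespace, is a hard
    error (the offending row is named).
    """
    direction = Direction(direction)
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ValueError(f"gene list {path} is empty")
    if header == "auto":
        first = rows[0][1].split("\t")[0].strip().lower()
        header = first in _HEADER_WORDS
    if header:
        rows = rows[1:]
        if not rows:
            raise ValueError(f"gene list {path} has a header but no data rows")

    records: list[GeneRecord] = []
    seen: set[str] = set()
    dropped = 0
    for lineno, ln in rows:
        symbol = ln.split("\t")[0].strip()
        if not symbol:
            raise ValueError(f"{path}:{lineno}: empty gene symbol")
        if any(c.isspace() for c in symbol):
            raise ValueError(
                f"{path}:{lineno}: gene symbol contains whitespace: {symbol!r}"
            )
        if symbol in seen:
            dropped += 1
            continue
        seen.add(symbol)
        records.append(GeneRecord(symbol, direction))
    if dropped:
        logger.warning("%s: dropped %d duplicate symbols", path, dropped)
    return records


def read_edge_list(
    path: str | Path, dialect: Literal["sif", "tsv"] = "tsv"
) -> InteractionNetwork:
    """Read an undirected edge list (SIF or two-column TSV).

    Self-loops and repeated pairs are silently collapsed (with a count in
    the log).  SIF lines with a single token contribute isolated nodes,
    mirroring Cytoscape's convention.
    """
    path = Path(path)
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    n_loops = n_dup = 0
    seen_edges: set[frozenset[str]] = set()
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        tok = ln.rstrip("\n").split("\t")
        if len(tok) == 1:
            tok = ln.split()
        if dialect == "sif":
            if len(tok) == 1:
                nodes.append(tok[0])
                continue
            if len(tok) < 3:
                raise ValueError(
                    f"{path}:{lineno}: SIF line needs 'node relation node'"
                )
            src, partners = tok[0], tok[2:]
        else:
            if len(tok) < 2:
                raise ValueError(
                    f"{path}:{lineno}: edge line has fewer than 2 columns"
                )
            src, partners = tok[0], [tok[1]]
        for dst in partners:
            if src == dst:
                n_loops += 1
                nodes.append(src)
                continue
            key = frozenset((src, dst))
            if key in seen_edges:
                n_dup += 1
                continue
            seen_edges.add(key)
            edges.append((src, dst))
    if n_loops or n_dup:
        logger.info(
            "%s: collapsed %d self-loops and %d duplicate edges",
            path, n_loops, n_dup,
        )
    return InteractionNetwork.from_edges(edges, nodes=nodes)


def write_edge_list(
    network: InteractionNetwork,
    path: str | Path,
    dialect: Literal["sif", "tsv"] = "tsv",
    relation: str = "pp",
) -> None:
    """Write a network as a canonical (sorted) edge list.

    Isolated nodes are representable only in SIF dialect (single-token
    lines); writing a network with isolated nodes as TSV is an error
    because the two-column dialect cannot round-trip them.
    """
    path = Path(path)
    lines = []
    covered: set[str] = set()
    for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
        covered.update((a, b))
        lines.append(f"{a}\t{relation}\t{b}" if dialect == "sif" else f"{a}\t{b}")
    isolated = sorted(set(network.graph.nodes) - covered)
    if isolated:
        if dialect == "tsv":
            raise ValueError(
                "TSV edge lists cannot represent isolated nodes "
                f"(e.g. {isolated[:3]}); use the SIF dialect"
            )
        lines.extend(isolated)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gmt(
    path: str | Path, universe: Iterable[str] | None = None
) -> AnnotationCatalog:
    """Read a standard GMT file (term, description, member genes...).

    The universe defaults to the union of all term members; pass an
    explicit ``universe`` to widen it.  Duplicate term ids and empty
    terms are hard errors.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        tok = ln.rstrip("\n").split("\t")
        if len(tok) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
            )
        tid, desc, members = tok[0], tok[1], frozenset(t for t in tok[2:] if t)
        if tid in terms:
            raise ValueError(f"{path}:{lineno}: duplicate term id {tid!r}")
        if not members:
            raise ValueError(f"{path}:{lineno}: term {tid!r} has no genes")
        terms[tid] = (desc, members)
    if not terms:
        raise ValueError(f"GMT file {path} is empty")
    full = frozenset().union(*(m for _, m in terms.values()))
    if universe is not None:
        full = full | frozenset(universe)
    return AnnotationCatalog(terms, full)


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> None:
    """Write a catalog in GMT format with sorted terms and members."""
    path = Path(path)
    lines = [
        "\t".join([tid, catalog.description(tid), *sorted(catalog.members(tid))])
        for tid in catalog.term_ids
    ]
    path.write_text("\n".join(lines) + "\n")


@dataclass
class PipelineConfig:
    """All knobs of the screening cascade, defaulting to the study values."""

    gene_list_up: str | None = None
    gene_list_down: str | None = None
    interactome: str | None = None
    interactome_dialect: Literal["sif", "tsv"] = "tsv"
    annotations: str | None = None
    hops: int = 1
    top_k: int = 20
    degree_panel_cutoff: float = 1200.0
    mcode: dict = field(default_factory=dict)
    min_module_score: float = 3.0
    min_module_nodes: int = 6
    kappa_threshold: float = 0.4
    enrich_top_n: int = 3


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
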