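"""Per-module over-representation analysis of annotation gene sets.

Each detected network module is tested against every annotation term it
overlaps, with a one-sided hypergeometric test (equivalent to Fisher's
exact right tail).  Raw p-values are corrected per module with the Holm
step-down procedure ("Bonferroni step down").  Terms whose gene
membership agrees strongly (Cohen's kappa >= 0.4 by default) are grouped
into single-linkage components, so the report can show one functional
group per family of redundant terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .mcode import NetworkModule
from .model import AnnotationCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeometric_p",
    "bonferroni_step_down",
    "kappa_matrix",
    "group_terms",
    "enrich_module",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One (module, term) test: overlap, p-values and kappa group."""

    term_id: str
    description: str
    module_id: str
    overlap: int
    term_size: int
    module_size: int
    universe_size: int
    p_value: float
    p_corrected: float
    kappa_group: int

    def __post_init__(self) -> None:
        assert self.overlap <= min(self.term_size, self.module_size)
        assert 0.0 <= self.p_value <= self.p_corrected <= 1.0


def hypergeometric_p(
    overlap: int, term_size: int, module_size: int, universe_size: int
) -> float:
    """Upper-tail P[X >= overlap] for X ~ Hypergeom(universe, term, module).

    The module is the drawn sample, the term the marked population.
    """
    if not 0 <= overlap <= min(term_size, module_size):
        raise ValueError("need 0 <= overlap <= min(term_size, module_size)")
    if max(term_size, module_size) > universe_size:
        raise ValueError("term and module must fit inside the universe")
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe_size, term_size, module_size))


def bonferroni_step_down(p_values: list[float]) -> list[float]:
    """Holm's sequentially rejective correction.

    Sort ascending; the i-th order statistic becomes
    max_{j<=i} min(1, (m-j+1) * p_(j)); results return in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def kappa_matrix(
    terms: AnnotationCatalog | dict[str, frozenset[str]],
    gene_scope: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Pairwise Cohen's kappa of term membership over ``gene_scope``.

    Each term is restricted to the scope; kappa compares the two binary
    membership vectors.  Identical vectors give 1.0 by convention, and a
    chance agreement of exactly 1 gives 0.0.
    """
    if isinstance(terms, AnnotationCatalog):
        sets = {t: terms.members(t) for t in terms.term_ids}
    else:
        sets = dict(terms)
    scope = frozenset(gene_scope)
    n = len(scope)
    if n == 0:
        raise ValueError("gene_scope is empty")
    ids = sorted(sets)
    restricted = {t: sets[t] & scope for t in ids}
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, ti in enumerate(ids):
        for tj in ids[i + 1 :]:
            a_set, b_set = restricted[ti], restricted[tj]
            mat.loc[ti, tj] = mat.loc[tj, ti] = _cohens_kappa(a_set, b_set, n)
    return mat


def _cohens_kappa(a_set: frozenset[str], b_set: frozenset[str], n: int) -> float:
    if a_set == b_set:
        return 1.0
    a = len(a_set & b_set)            # in both
    b = len(a_set - b_set)            # A only
    c = len(b_set - a_set)            # B only
    d = n - a - b - c                 # in neither
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def group_terms(kappa: pd.DataFrame, threshold: float = 0.4) -> dict[str, int]:
    """Single-linkage grouping: connected components of kappa >= threshold.

    Group ids are the index (in the sorted term-id list) of each
    component's lexicographically smallest member, so grouping is
    invariant to input order.
    """
    ids = sorted(kappa.index)
    pos = {t: i for i, t in enumerate(ids)}
    parent = {t: t for t in ids}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, ti in enumerate(ids):
        for tj in ids[i + 1 :]:
            if kappa.loc[ti, tj] >= threshold:
                ri, rj = find(ti), find(tj)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return {t: pos[find(t)] for t in ids}


def enrich_module(
    module: NetworkModule,
    catalog: AnnotationCatalog,
    alpha: float = 0.05,
    top_n: int = 3,
    kappa_threshold: float = 0.4,
    module_id: str | None = None,
) -> list[EnrichmentResult]:
    """Test every overlapping term against one module and report the top hits.

    Module members outside the catalog universe are dropped with a
    warning.  Correction is applied across all tested terms of this
    module; results are sorted by corrected p ascending (ties by term id)
    and the first ``top_n`` returned, annotated with kappa group ids
    computed over the module's gene scope.  ``alpha`` is informational
    (callers compare ``p_corrected`` against it); it does not truncate
    the output.
    """
    if not module.members:
        raise ValueError("module has no members")
    scope = set(module.members) & set(catalog.universe)
    outside = set(module.members) - scope
    if outside:
        logger.warning(
            "%d module members outside annotation universe (e.g. %s)",
            len(outside), sorted(outside)[:5],
        )
    if not scope:
        raise ValueError("no module member is in the annotation universe")
    mid = module_id if module_id is not None else module.seed
    universe_size = len(catalog.universe)

    tested: list[tuple[str, int, int]] = []
    for tid in catalog.term_ids:
        overlap = len(catalog.members(tid) & scope)
        if overlap >= 1:
            tested.append((tid, overlap, len(catalog.members(tid))))
    if not tested:
        return []

    raw = [
        hypergeometric_p(ov, tsize, len(scope), universe_size)
        for _, ov, tsize in tested
    ]
    corrected = bonferroni_step_down(raw)

    kappa = kappa_matrix({t: catalog.members(t) for t, _, _ in tested}, scope)
    groups = group_terms(kappa, kappa_threshold)

    results = [
        EnrichmentResult(
            term_id=tid,
            description=catalog.description(tid),
            module_id=mid,
            overlap=ov,
            term_size=tsize,
            module_size=len(scope),
            universe_size=universe_size,
            p_value=p,
            p_corrected=pc,
            kappa_group=groups[tid],
        )
        for (tid, ov, tsize), p, pc in zip(tested, raw, corrected)
    ]
    results.sort(key=lambda r: (r.p_corrected, r.term_id))
    return results[:top_n]
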