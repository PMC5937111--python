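"""Enrichment: hypergeometric tail, Holm correction, kappa grouping."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppiscreen import (
    AnnotationCatalog,
    NetworkModule,
    bonferroni_step_down,
    enrich_module,
    group_terms,
    hypergeometric_p,
    kappa_matrix,
)


def enumerate_tail(overlap, term_size, module_size, universe_size):
    """Oracle: exact P[X >= overlap] by enumerating all draws."""
    total = math.comb(universe_size, module_size)
    hits = sum(
        math.comb(term_size, k) * math.comb(universe_size - term_size, module_size - k)
        for k in range(overlap, min(term_size, module_size) + 1)
    )
    return hits / total


def holm_oracle(ps):
    """Direct Holm definition, computed independently."""
    m = len(ps)
    indexed = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    running = 0.0
    for rank, i in enumerate(indexed):
        running = max(running, min(1.0, (m - rank) * ps[i]))
        out[i] = running
    return out


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_p(0, 5, 6, 20) == 1.0

    def test_term_equals_universe(self):
        assert hypergeometric_p(6, 20, 6, 20) == pytest.approx(1.0)

    def test_matches_enumeration_example(self):
        got = hypergeometric_p(4, 5, 6, 20)
        assert got == pytest.approx(enumerate_tail(4, 5, 6, 20), abs=1e-12)

    @pytest.mark.parametrize("universe", [10, 17, 25])
    def test_matches_enumeration_exhaustively(self, universe):
        for term in range(1, universe + 1, 3):
            for module in range(1, universe + 1, 4):
                for overlap in range(0, min(term, module) + 1):
                    got = hypergeometric_p(overlap, term, module, universe)
                    want = enumerate_tail(overlap, term, module, universe)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_p(6, 5, 6, 20)
        with pytest.raises(ValueError):
            hypergeometric_p(1, 25, 6, 20)


class TestHolm:
    def test_single_p_unchanged(self):
        assert bonferroni_step_down([0.04]) == [0.04]

    def test_equal_ps(self):
        assert bonferroni_step_down([0.01, 0.01, 0.01]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_direct_formula(self, ps):
        assert bonferroni_step_down(ps) == pytest.approx(holm_oracle(ps))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, ps):
        adj = bonferroni_step_down(ps)
        assert all(0.0 <= a <= 1.0 for a in adj)
        assert all(a >= p for a, p in zip(adj, ps))
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        ranked = [adj[i] for i in order]
        assert all(a <= b for a, b in zip(ranked, ranked[1:]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            ps = rng.uniform(size=int(rng.integers(1, 7)))
            want = multipletests(ps, method="holm")[1]
            assert bonferroni_step_down(list(ps)) == pytest.approx(list(want))


def kappa_2x2_oracle(a_set, b_set, scope):
    va = [g in a_set for g in sorted(scope)]
    vb = [g in b_set for g in sorted(scope)]
    if va == vb:
        return 1.0
    n = len(scope)
    a = sum(x and y for x, y in zip(va, vb))
    b = sum(x and not y for x, y in zip(va, vb))
    c = sum(y and not x for x, y in zip(va, vb))
    d = n - a - b - c
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    return 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)


class TestKappa:
    def test_identical_sets(self):
        m = kappa_matrix({"A": frozenset("xy"), "B": frozenset("xy")}, set("xyzw"))
        assert m.loc["A", "B"] == 1.0

    def test_perfect_disagreement(self):
        m = kappa_matrix(
            {"A": frozenset(["g1", "g2"]), "B": frozenset(["g3", "g4"])},
            {"g1", "g2", "g3", "g4"},
        )
        assert m.loc["A", "B"] == pytest.approx(-1.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scope = {f"g{i}" for i in range(int(rng.integers(2, 10)))}
        genes = sorted(scope)
        a = frozenset(g for g in genes if rng.random() < 0.5)
        b = frozenset(g for g in genes if rng.random() < 0.5)
        m = kappa_matrix({"A": a, "B": b}, scope)
        assert m.loc["A", "B"] == pytest.approx(kappa_2x2_oracle(a, b, scope))
        assert m.loc["A", "B"] == m.loc["B", "A"]


class TestGroupTerms:
    def _kappa(self, pairs, ids):
        import pandas as pd

        ids = list(ids)
        m = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for (a, b), k in pairs.items():
            m.loc[a, b] = m.loc[b, a] = k
        return m

    def test_all_below_threshold_are_singletons(self):
        m = self._kappa({("A", "B"): 0.1, ("B", "C"): 0.2, ("A", "C"): 0.3}, "ABC")
        groups = group_terms(m)
        assert len(set(groups.values())) == 3

    def test_transitive_closure(self):
        m = self._kappa({("A", "B"): 0.5, ("B", "C"): 0.5, ("A", "C"): 0.1}, "ABC")
        groups = group_terms(m)
        assert groups["A"] == groups["B"] == groups["C"]

    def test_order_invariance(self):
        pairs = {("A", "B"): 0.6, ("C", "D"): 0.9, ("B", "D"): 0.1}
        g1 = group_terms(self._kappa(pairs, "ABCD"))
        g2 = group_terms(self._kappa(pairs, "DCBA"))
        assert g1 == g2


class TestEnrichModule:
    def _catalog(self):
        return AnnotationCatalog(
            {
                "T1": ("covers module", frozenset({"a", "b", "c"})),
                "T2": ("background", frozenset({"c", "d", "e", "f"})),
            },
            frozenset("abcdefgh"),
        )

    def _module(self, *members):
        ms = frozenset(members)
        return NetworkModule(ms, min(ms), 4.0, len(ms), len(ms))

    def test_containing_term_ranks_first(self):
        results = enrich_module(self._module("a", "b", "c"), self._catalog())
        assert results[0].term_id == "T1"
        assert results[0].overlap == 3
        assert results[0].p_corrected >= results[0].p_value

    def test_top_n_larger_than_tested_returns_all(self):
        results = enrich_module(self._module("a", "b"), self._catalog(), top_n=10)
        assert [r.term_id for r in results] == ["T1"]

    def test_members_outside_universe_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            results = enrich_module(self._module("a", "b", "zzz"), self._catalog())
        assert results[0].module_size == 2
        assert "universe" in caplog.text

    def test_empty_module_is_error(self):
        mod = NetworkModule(frozenset(), "x", 0.0, 0, 0)
        with pytest.raises(ValueError):
            enrich_module(mod, self._catalog())
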