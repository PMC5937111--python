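"""Over-representation statistics on a toy annotation catalog.

Shows the hypergeometric upper tail, the Holm ("Bonferroni step down")
correction, and Cohen's-kappa term grouping on a 20-gene universe.
"""

from ppiscreen import (
    AnnotationCatalog, NetworkModule, bonferroni_step_down, enrich_module,
    group_terms, hypergeometric_p, kappa_matrix,
)

genes = [f"g{i}" for i in range(20)]
catalog = AnnotationCatalog(
    {
        "T:cycle": ("cell cycle", frozenset(genes[:6])),
        "T:mitosis": ("mitotic division", frozenset(genes[1:6])),
        "T:transport": ("ion transport", frozenset(genes[10:18])),
    },
    frozenset(genes),
)

p = hypergeometric_p(overlap=4, term_size=5, module_size=6, universe_size=20)
print(f"P[overlap >= 4 | term 5, module 6, universe 20] = {p:.3e}")

print("Holm on [0.01, 0.04, 0.03]:",
      [round(q, 3) for q in bonferroni_step_down([0.01, 0.04, 0.03])])

module = NetworkModule(frozenset(genes[:6]), "g0", 5.0, 6, 12)
for r in enrich_module(module, catalog):
    print(f"{r.term_id}: overlap {r.overlap}/{r.term_size}, "
          f"p={r.p_value:.2e}, p_corr={r.p_corrected:.2e}, "
          f"kappa group {r.kappa_group}")

kappa = kappa_matrix(catalog, frozenset(genes))
groups = group_terms(kappa, threshold=0.4)
print("kappa groups (cycle/mitosis agree, transport is separate):", groups)
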