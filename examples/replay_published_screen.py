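"""Replay the published laryngeal-cancer screening cascade.

Loads the packaged printed tables (differentially expressed protein
lists, top-20 degree and betweenness blocks of the up- and down-regulated
networks, and the module hub table), then runs every screening stage:
top-k hub/bottleneck selection, intersection, module-residency filtering
and the degree >= 1200 panel cutoff.
"""

from ppiscreen.fixtures import load_gene_records, screen_printed_tables

up = load_gene_records("up")
down = load_gene_records("down")
print(f"differentially expressed proteins: {len(up)} up, {len(down)} down, "
      f"{len(up) + len(down)} total")

res = screen_printed_tables()
print(f"hub-bottlenecks: {len(res['up_hub_bottlenecks'])} up + "
      f"{len(res['down_hub_bottlenecks'])} down = {len(res['hub_bottlenecks'])}")
print(f"module-resident hub-bottlenecks: {len(res['module_resident'])}")
print(f"  {sorted(res['module_resident'])}")
print(f"biomarker panel (degree >= 1200): {sorted(res['panel'])}")

# The panel members are the candidates every screening stage agreed on:
# top-20 by connectivity AND by betweenness, members of a dense network
# module, and among the most connected proteins overall.
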