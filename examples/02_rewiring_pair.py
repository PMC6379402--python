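"""Detect rewired genes between a control and a case condition.

Plants 10 rewired genes (80% of their edges re-routed in the case
condition) in a 150-gene multiplex pair, builds the two integrated
networks with a shared initialization and common thresholds, ranks genes
by the GDV distance of their wiring between conditions, and tests whether
the planted genes are enriched among the top-ranked.
"""

from icell import SolverConfig, build_icell_pair, fuse_pair
from icell.rewiring import rewiring_scores, top_rewired_enrichment
from icell.synthetic import simulate_condition_pair, simulate_multiplex

base = simulate_multiplex(n=150, k=3, m=3, p_in=0.3, p_out=0.02, seed=0)
pair = simulate_condition_pair(base, n_rewired=10, rewiring_strength=0.8, seed=1)

res_control, res_case = fuse_pair(
    pair.control, pair.case, SolverConfig(k=3, max_iter=50)
)
icell_control, icell_case = build_icell_pair(
    res_control.G, res_case.G, pair.control.gene_index, threshold_fraction=0.01
)

ranking = rewiring_scores(icell_control, icell_case, pair.control.gene_index)
top20 = set(ranking.top(20))
hits = len(top20 & pair.rewired_genes)
print(f"planted rewired genes found in the top 20 of 150: {hits}/10")

enrich = top_rewired_enrichment(
    ranking,
    markers=pair.rewired_genes,
    background=pair.control.gene_index,
    top_n=20,
)
print(
    f"marker enrichment in the top 20: fold={enrich.fold:.1f}, "
    f"p={enrich.p_raw:.2e} ({enrich.direction})"
)
print("-> high fold and tiny p: the rewiring score pinpoints the genes whose")
print("   wiring actually changed between the two conditions.")
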