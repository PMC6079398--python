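"""Gene-set over-representation of the refined network.

Tests the refined-network genes (foreground) against all identified
genes (background) over a planted function set, a phenotype set and
random decoys; also prints the single-set fraction comparison in the
form 'x of n (y%)'.
"""

from sscnet import (
    EdgeList,
    SimConfig,
    enrich_sets,
    filter_low_quality,
    fraction_comparison,
    induce_refined_network,
    optimal_cutoff,
    scan_cutoffs,
    score_table,
    select_candidates,
    simulate_expression,
    simulate_gene_sets,
    simulate_interactions,
)

cfg = SimConfig(seed=42)
table, truth = simulate_expression(cfg)
scores = score_table(filter_low_quality(table))
best = optimal_cutoff(scan_cutoffs(scores, sorted(truth.marker_ids)))
candidates = select_candidates(scores, best.cutoff)
edges, truth = simulate_interactions(truth, cfg)
net = induce_refined_network(
    candidates,
    EdgeList(edges=edges.edges[edges.edges["score"] >= 0.7].reset_index(drop=True),
             score_threshold=0.7),
)

foreground = sorted(net.graph.nodes)
background = scores.data["gene"].tolist()
sets = simulate_gene_sets(truth, n_decoy_sets=5, seed=cfg.seed)

rows = enrich_sets(foreground, background, sets)
print(rows[["set_id", "n_fg_in_set", "n_fg", "n_bg_in_set", "n_bg",
            "p_value", "significant"]].to_string(index=False))

fg_pct, bg_pct, p = fraction_comparison(
    foreground, background, sets.members("true_function")
)
k = rows.set_index("set_id").loc["true_function", "n_fg_in_set"]
print(f"\n{k} of {len(foreground)} network genes ({fg_pct}%) are in the planted")
print(f"function set, vs {bg_pct}% of all identified genes (p = {p:.2e}).")
print("Decoy sets should be non-significant: they are size-matched random draws.")
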