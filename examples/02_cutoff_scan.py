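"""Find the expression-index cutoff that best enriches a reference set.

Simulates a 1000-gene transcriptome with 8 planted marker genes, scans
every 0.001-wide index cutoff for Fisher's-exact enrichment of the
markers, and prints the optimal cutoff (minimal p; shortest list on
ties) and the inclusive cutoff (largest one retaining every marker).
"""

from sscnet import (
    SimConfig,
    filter_low_quality,
    inclusive_cutoff,
    marker_diagnostics,
    optimal_cutoff,
    scan_cutoffs,
    score_table,
    select_candidates,
    simulate_expression,
)

cfg = SimConfig(n_genes=1000, n_markers=8, n_signal=50, seed=42)
table, truth = simulate_expression(cfg)
scores = score_table(filter_low_quality(table))
markers = sorted(truth.marker_ids)

diag = marker_diagnostics(scores, markers)
print(f"markers found: {diag.n_found}/8; abundance vs fold change "
      f"r = {diag.pearson_r:.2f} (p = {diag.p_value:.3f})")
print(f"marker expression-index range: "
      f"{diag.index_range[0]:.3f} to {diag.index_range[1]:.3f}")

scan = scan_cutoffs(scores, markers, step=0.001)
best = optimal_cutoff(scan)
incl = inclusive_cutoff(scores, markers)

print(f"\noptimal cutoff  {best.cutoff:.3f}: {best.n_pos_selected}/8 markers in "
      f"{best.n_selected} candidates (p = {best.p_value:.2e})")
print(f"inclusive cutoff {incl.cutoff:.3f}: {incl.n_pos_selected}/8 markers in "
      f"{incl.n_selected} genes (p = {incl.p_value:.2e})")

candidates = select_candidates(scores, best.cutoff)
planted = truth.marker_ids | truth.signal_ids
recall = len(set(candidates) & planted) / len(planted)
print(f"\nrecall of all {len(planted)} planted genes at the optimum: {recall:.2f}")
print("The negative r mirrors the biological regime: abundant markers change the")
print("least, so ranking by fold change alone would bury them.")
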