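import math

import numpy as np
import pandas as pd
import pytest

from sscnet import (
    GeneScoreTable,
    InputError,
    SimConfig,
    fisher_enrichment,
    inclusive_cutoff,
    optimal_cutoff,
    scan_cutoffs,
    score_table,
    select_candidates,
    simulate_expression,
)

from _oracles import hypergeom_upper_tail
from conftest import make_table


def scores_from_indices(indices: dict[str, float]) -> GeneScoreTable:
    """Minimal score table with prescribed expression indices."""
    df = pd.DataFrame(
        {
            "gene": list(indices),
            "fpkm_a": 2.0,
            "fpkm_b": 1.0,
            "expression_index": list(indices.values()),
        }
    )
    return GeneScoreTable(data=df)


class TestFisherEnrichment:
    def test_empty_selection_has_p_one(self):
        assert fisher_enrichment(0, 0, 8, 1000) == 1.0

    def test_perfect_selection_closed_form(self):
        # C(8,8) * C(8,0) / C(16,8) = 1/12870
        assert fisher_enrichment(8, 8, 8, 16) == pytest.approx(1 / 12870, rel=1e-9)

    def test_partial_overlap_tail_sum(self):
        # exhaustive tail sum over X = 2..5: P(X=0) = 0.58375,
        # P(X=1) = 0.33939, so P(X >= 2) = 0.076857
        expected = hypergeom_upper_tail(2, 100, 5, 10)
        assert expected == pytest.approx(0.076857, abs=1e-6)
        assert fisher_enrichment(2, 10, 5, 100) == pytest.approx(expected, abs=1e-12)

    def test_exhaustive_small_margins_vs_oracle(self):
        for n_total in range(1, 17):
            for n_pos in range(n_total + 1):
                for n_sel in range(n_total + 1):
                    for k in range(max(0, n_sel - (n_total - n_pos)),
                                   min(n_sel, n_pos) + 1):
                        got = fisher_enrichment(k, n_sel, n_pos, n_total)
                        want = hypergeom_upper_tail(k, n_total, n_pos, n_sel)
                        assert got == pytest.approx(want, abs=1e-10), (
                            k, n_sel, n_pos, n_total
                        )

    def test_random_margins_up_to_sixty_vs_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(1500):
            n_total = int(rng.integers(1, 61))
            n_pos = int(rng.integers(0, n_total + 1))
            n_sel = int(rng.integers(0, n_total + 1))
            lo = max(0, n_sel - (n_total - n_pos))
            k = int(rng.integers(lo, min(n_sel, n_pos) + 1))
            got = fisher_enrichment(k, n_sel, n_pos, n_total)
            want = hypergeom_upper_tail(k, n_total, n_pos, n_sel)
            assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("args", [(5, 4, 8, 100), (2, 10, 1, 100), (3, 10, 5, 8)])
    def test_inconsistent_margins_rejected(self, args):
        with pytest.raises(InputError):
            fisher_enrichment(*args)


class TestScanCutoffs:
    def test_uniform_indices_never_discriminate(self):
        scores = scores_from_indices({f"g{i}": 0.5 for i in range(10)})
        scan = scan_cutoffs(scores, ["g0", "g1"], step=0.1)
        assert (scan.rows["n_selected"] == 10).all()
        assert (scan.rows["p_value"] == 1.0).all()

    def test_perfect_separation_attains_closed_form_minimum(self):
        idx = {f"null{i}": 0.001 + i * 0.004 for i in range(95)}
        idx |= {f"pos{i}": 0.9 + i * 0.01 for i in range(5)}
        scores = scores_from_indices(idx)
        scan = scan_cutoffs(scores, [f"pos{i}" for i in range(5)])
        pmin = scan.rows["p_value"].min()
        assert pmin == pytest.approx(1 / math.comb(100, 5), rel=1e-9)
        best = optimal_cutoff(scan)
        assert best.n_selected == 5 and best.n_pos_selected == 5

    def test_zero_cutoff_selects_everything(self, four_gene_scores):
        scan = scan_cutoffs(four_gene_scores, ["g1"])
        assert scan.rows.iloc[0]["cutoff"] == 0.0
        assert scan.rows.iloc[0]["n_selected"] == 4

    def test_counts_non_increasing_along_grid(self):
        table, truth = simulate_expression(SimConfig(n_genes=300, seed=7))
        scores = score_table(table)
        scan = scan_cutoffs(scores, sorted(truth.marker_ids), step=0.01)
        assert (np.diff(scan.rows["n_selected"]) <= 0).all()
        assert (np.diff(scan.rows["n_pos_selected"]) <= 0).all()
        assert (scan.rows["n_pos_selected"]
                <= np.minimum(scan.rows["n_selected"], scan.n_pos_total)).all()

    def test_missing_all_positives_rejected(self, four_gene_scores):
        with pytest.raises(InputError, match="ghost"):
            scan_cutoffs(four_gene_scores, ["ghost"])

    def test_gene_at_grid_point_is_selected_inclusively(self):
        scores = scores_from_indices({"a": 0.3, "b": 0.2})
        scan = scan_cutoffs(scores, ["a"], step=0.1)
        row = scan.rows[scan.rows["cutoff"].round(6) == 0.3].iloc[0]
        assert row["n_selected"] == 1


class TestOptimalCutoff:
    def test_argmin_of_p(self):
        scan = scan_cutoffs(
            scores_from_indices({"p1": 0.25, "p2": 0.28, "n1": 0.05, "n2": 0.31}),
            ["p1", "p2"],
            step=0.01,
        )
        best = optimal_cutoff(scan)
        assert best.p_value == scan.rows["p_value"].min()
        assert best.mode == "optimal"

    def test_ties_broken_toward_largest_cutoff(self):
        # between 0.11 and 0.25 the selection {p1, p2, n2} never changes,
        # so the p-value plateaus; the reported optimum must be the top
        # of the plateau
        scan = scan_cutoffs(
            scores_from_indices({"p1": 0.30, "p2": 0.25, "n1": 0.10, "n2": 0.40}),
            ["p1", "p2"],
            step=0.01,
        )
        best = optimal_cutoff(scan)
        tied = scan.rows[scan.rows["p_value"] == best.p_value]
        assert best.cutoff == tied["cutoff"].max()

    def test_flat_p_flags_non_significance(self):
        scan = scan_cutoffs(scores_from_indices({"a": 0.5, "b": 0.5}), ["a"], step=0.1)
        best = optimal_cutoff(scan)
        assert not best.significant

    def test_permutation_null_rarely_significant_at_strict_level(self):
        # with positives drawn uniformly at random there is no signal:
        # the scan's min-p is multiplicity-inflated, but extreme
        # significance should stay rare
        hits = 0
        for seed in range(15):
            table, _ = simulate_expression(SimConfig(n_genes=200, seed=seed))
            scores = score_table(table)
            rng = np.random.default_rng(seed + 1000)
            fake = list(rng.choice(scores.data["gene"], size=8, replace=False))
            best = optimal_cutoff(scan_cutoffs(scores, fake, step=0.01))
            hits += best.p_value < 1e-4
        assert hits <= 2


class TestInclusiveCutoff:
    def test_floor_of_minimum_positive_index(self):
        scores = scores_from_indices({"a": 0.41, "b": 0.16, "n": 0.02})
        res = inclusive_cutoff(scores, ["a", "b"])
        assert res.cutoff == pytest.approx(0.16)
        assert res.n_pos_selected == 2
        assert res.mode == "inclusive"

    def test_grid_flooring_of_off_grid_index(self):
        scores = scores_from_indices({"a": 0.2675, "n": 0.01})
        res = inclusive_cutoff(scores, ["a"])
        assert res.cutoff == pytest.approx(0.267)

    def test_single_positive_at_table_maximum(self):
        scores = scores_from_indices({"a": 0.9, "n": 0.1})
        res = inclusive_cutoff(scores, ["a"])
        assert res.cutoff == pytest.approx(0.9)
        assert res.n_selected >= 1

    def test_retains_every_found_positive(self):
        table, truth = simulate_expression(SimConfig(n_genes=400, seed=11))
        scores = score_table(table)
        res = inclusive_cutoff(scores, sorted(truth.marker_ids))
        assert res.n_pos_selected == len(truth.marker_ids)


class TestSelectCandidates:
    def test_boundaries(self, four_gene_scores):
        assert len(select_candidates(four_gene_scores, 0.0)) == 4
        assert select_candidates(four_gene_scores, 99.0) == []

    def test_worked_table_at_cutoff(self, four_gene_scores):
        assert select_candidates(four_gene_scores, 0.70) == ["g1", "g4"]

    def test_sorted_by_descending_index_then_gene(self):
        scores = scores_from_indices({"z": 0.5, "a": 0.5, "m": 0.9})
        assert select_candidates(scores, 0.1) == ["m", "a", "z"]


class TestRecovery:
    def test_planted_positives_recovered_across_seeds(self):
        """With index-separated planted positives the optimum must reach
        p < 0.001 and recall >= 0.8 of the planted reference genes."""
        for seed in range(20):
            table, truth = simulate_expression(SimConfig(seed=seed))
            scores = score_table(table)
            positives = sorted(truth.signal_ids)
            best = optimal_cutoff(scan_cutoffs(scores, positives))
            selected = set(select_candidates(scores, best.cutoff))
            recall = len(selected & truth.signal_ids) / len(truth.signal_ids)
            assert best.p_value < 1e-3
            assert recall >= 0.8
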