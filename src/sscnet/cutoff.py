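"""Dynamic cutoff scan: find the expression-index threshold that best
enriches a positive-reference gene set.

Every grid threshold from 0 to the maximum observed index (step 0.001
by default) is evaluated: genes with index >= cutoff are "selected",
and a one-sided Fisher's exact test compares the fraction of positive
genes among the selected set against the rest of the identified-gene
universe.  As the cutoff rises the enrichment significance typically
rises and then falls; the optimum is the grid point with minimal p
(ties broken toward the largest cutoff, i.e. the smallest gene list).
A second, "inclusive" cutoff is the largest grid value that still
retains every positive gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .scoring import GeneScoreTable

logger = logging.getLogger("sscnet.cutoff")

#: absolute slack when comparing an index against a grid cutoff, so that
#: a gene whose index equals a grid point is never lost to float rounding
GRID_EPS = 1e-9


def fisher_enrichment(
    n_pos_sel: int, n_sel: int, n_pos_total: int, n_total: int
) -> float:
    """One-sided (enrichment) Fisher's exact p for a 2x2 selection table.

    The table is [selected & positive, selected & negative; unselected &
    positive, unselected & negative]; the p-value equals the
    hypergeometric upper tail P(X >= n_pos_sel) when drawing ``n_sel``
    genes from ``n_total`` of which ``n_pos_total`` are positive.
    """
    if not (0 <= n_pos_sel <= n_sel <= n_total):
        raise InputError(
            f"inconsistent margins: 0 <= {n_pos_sel} <= {n_sel} <= {n_total} violated"
        )
    if not (n_pos_sel <= n_pos_total <= n_total):
        raise InputError(
            f"inconsistent margins: {n_pos_sel} <= {n_pos_total} <= {n_total} violated"
        )
    if n_sel - n_pos_sel > n_total - n_pos_total:
        raise InputError("inconsistent margins: more selected negatives than negatives")
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(n_pos_sel - 1, n_total, n_pos_total, n_sel))


@dataclass(frozen=True)
class CutoffScan:
    """Full scan grid.

    ``rows`` columns: cutoff, n_selected, n_pos_selected, p_value.
    Cutoffs are strictly increasing; selected counts are non-increasing.
    """

    step: float
    n_total: int
    n_pos_total: int
    rows: pd.DataFrame

    def write(self, path, sep: str = "\t") -> None:
        self.rows.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    p_value: float
    n_selected: int
    n_pos_selected: int
    mode: str  # "optimal" | "inclusive"
    significant: bool

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "p_value": self.p_value,
            "n_selected": self.n_selected,
            "n_pos_selected": self.n_pos_selected,
            "mode": self.mode,
            "significant": self.significant,
        }


def _positive_indices(
    scores: GeneScoreTable, positives: Iterable[str]
) -> tuple[np.ndarray, list[str]]:
    """Expression indices of the positives found in the table (case-insensitive)."""
    positives = list(positives)
    if not positives:
        raise InputError("positive-reference set is empty")
    rows = scores.index_of(positives)
    found_keys = set(rows["gene"].str.lower())
    missing = [p for p in positives if p.strip().lower() not in found_keys]
    if missing:
        logger.warning(
            "%d positive gene(s) absent from the score table: %s",
            len(missing), ", ".join(missing),
        )
    if rows.empty:
        raise InputError(
            "none of the positive genes are present in the score table: "
            + ", ".join(positives)
        )
    return rows["expression_index"].to_numpy(float), missing


def scan_cutoffs(
    scores: GeneScoreTable,
    positives: Iterable[str],
    step: float = 0.001,
) -> CutoffScan:
    """Evaluate every grid cutoff from 0 to the maximum index inclusive.

    Selection rule is closed: ``expression_index >= cutoff``.  Each row
    carries the one-sided enrichment p against the full scored-gene
    universe.
    """
    if step <= 0:
        raise InputError(f"step must be > 0, got {step}")
    pos_idx, _ = _positive_indices(scores, positives)

    all_idx = np.sort(scores.data["expression_index"].to_numpy(float))
    pos_sorted = np.sort(pos_idx)
    n_total = all_idx.size
    n_pos_total = pos_sorted.size

    n_grid = int(math.floor(all_idx[-1] / step + GRID_EPS)) + 1
    cutoffs = np.arange(n_grid) * step
    # number of indices >= cutoff, with slack so grid-equal values count
    n_selected = n_total - np.searchsorted(all_idx, cutoffs - GRID_EPS, side="left")
    n_pos_selected = n_pos_total - np.searchsorted(pos_sorted, cutoffs - GRID_EPS, side="left")
    p = stats.hypergeom.sf(n_pos_selected - 1, n_total, n_pos_total, n_selected)

    rows = pd.DataFrame(
        {
            "cutoff": cutoffs,
            "n_selected": n_selected.astype(int),
            "n_pos_selected": n_pos_selected.astype(int),
            "p_value": p,
        }
    )
    return CutoffScan(step=step, n_total=n_total, n_pos_total=n_pos_total, rows=rows)


def optimal_cutoff(scan: CutoffScan, alpha: float = 0.05) -> CutoffResult:
    """Grid cutoff with minimal enrichment p.

    Ties go to the *largest* cutoff — the shortest candidate list
    achieving the same significance ("maximum positive results as well
    as minimum negative results").  ``significant`` is False when even
    the minimum p fails ``alpha``.
    """
    rows = scan.rows
    if rows.empty:
        raise InputError("empty cutoff scan")
    pmin = rows["p_value"].min()
    best = rows[rows["p_value"] == pmin].iloc[-1]
    significant = bool(pmin < alpha)
    if not significant:
        logger.warning("no cutoff reaches significance (min p = %.3g >= %g)", pmin, alpha)
    return CutoffResult(
        cutoff=float(best["cutoff"]),
        p_value=float(best["p_value"]),
        n_selected=int(best["n_selected"]),
        n_pos_selected=int(best["n_pos_selected"]),
        mode="optimal",
        significant=significant,
    )


def inclusive_cutoff(
    scores: GeneScoreTable,
    positives: Iterable[str],
    step: float = 0.001,
    alpha: float = 0.05,
) -> CutoffResult:
    """Largest grid cutoff that still selects every (found) positive.

    The cutoff is the grid floor of the minimum positive expression
    index; positives missing from the table are excluded with a warning.
    """
    if step <= 0:
        raise InputError(f"step must be > 0, got {step}")
    pos_idx, _ = _positive_indices(scores, positives)
    cutoff = math.floor(min(pos_idx) / step + GRID_EPS) * step

    all_idx = scores.data["expression_index"].to_numpy(float)
    sel = all_idx >= cutoff - GRID_EPS
    n_selected = int(sel.sum())
    n_pos_selected = int((pos_idx >= cutoff - GRID_EPS).sum())
    p = fisher_enrichment(n_pos_selected, n_selected, len(pos_idx), all_idx.size)
    return CutoffResult(
        cutoff=float(cutoff),
        p_value=p,
        n_selected=n_selected,
        n_pos_selected=n_pos_selected,
        mode="inclusive",
        significant=bool(p < alpha),
    )


def select_candidates(scores: GeneScoreTable, cutoff: float) -> list[str]:
    """Genes with expression_index >= cutoff, by descending index
    (ties alphabetically by gene id)."""
    df = scores.data
    sel = df[df["expression_index"] >= cutoff - GRID_EPS]
    sel = sel.sort_values(
        ["expression_index", "gene"], ascending=[False, True], kind="mergesort"
    )
    return sel["gene"].tolist()
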