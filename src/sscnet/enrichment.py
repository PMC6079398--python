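"""Gene-set over-representation analysis (Fisher's exact).

A foreground list (typically the refined-network genes) is compared
against a background universe (all identified genes after the FPKM
filter).  For each gene set the 2x2 table uses disjoint margins —
foreground vs background-minus-foreground — and a one-sided
(enrichment) p-value; membership is intersected with the background
first so out-of-universe annotations cannot distort the margins.
No multiple-testing correction is applied by default (raw p < alpha);
a Benjamini–Hochberg option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cutoff import fisher_enrichment
from .errors import InputError

logger = logging.getLogger("sscnet.enrichment")


@dataclass(frozen=True)
class GeneSets:
    """Named gene sets, e.g. GO biological-process or KEGG pathway sets.

    ``sets`` maps set_id -> (set_name, frozenset of member symbols).
    Member case is preserved; matching downstream is case-insensitive.
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


def read_gmt(path: str | Path) -> GeneSets:
    """Parse a GMT file: ``set_id <tab> description <tab> member...``.

    Duplicate members within a line are stored once; lines with fewer
    than three fields or an empty member list are skipped with a
    warning.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if len(fields) < 3 or not members:
                n_skipped += 1
                logger.warning("%s:%d: skipped gene-set line with no members", path, lineno)
                continue
            set_id = fields[0].strip()
            if set_id in sets:
                raise InputError(f"{path}: duplicate set id {set_id!r}")
            sets[set_id] = (fields[1].strip(), members)
    if n_skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, n_skipped)
    return GeneSets(sets=sets)


def write_gmt(sets: GeneSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (name, members) in sets.sets.items():
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")


def _lower(genes: Iterable[str]) -> set[str]:
    return {g.strip().lower() for g in genes}


def enrich_sets(
    foreground: Iterable[str],
    background: Iterable[str],
    sets: GeneSets,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """One row of Fisher's-exact enrichment per gene set.

    Columns: set_id, set_name, n_fg_in_set, n_fg, n_bg_in_set, n_bg,
    p_value, significant (p < alpha) — sorted by ascending p (ties by
    set_id).  ``fdr=True`` adds a ``q_value`` column (Benjamini–
    Hochberg) and bases ``significant`` on it instead.
    """
    fg = _lower(foreground)
    bg = _lower(background)
    if not bg:
        raise InputError("background universe is empty")
    offenders = fg - bg
    if offenders:
        raise InputError(
            "foreground genes absent from background: " + ", ".join(sorted(offenders))
        )

    rows = []
    for set_id, (name, members) in sets.sets.items():
        in_bg = _lower(members) & bg
        k = len(in_bg & fg)
        p = fisher_enrichment(k, len(fg), len(in_bg), len(bg))
        rows.append(
            {
                "set_id": set_id,
                "set_name": name,
                "n_fg_in_set": k,
                "n_fg": len(fg),
                "n_bg_in_set": len(in_bg),
                "n_bg": len(bg),
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_id", "set_name", "n_fg_in_set", "n_fg",
                 "n_bg_in_set", "n_bg", "p_value"],
    )
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["q_value"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    out = out.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    return out


def fraction_comparison(
    foreground: Iterable[str],
    background: Iterable[str],
    one_set: Iterable[str],
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Compare one gene set's percentage in foreground vs background.

    Returns ``(fg_pct, bg_pct, p)`` with the percentages rounded to one
    decimal for reporting (p from the same disjoint-margin Fisher
    machinery as :func:`enrich_sets`).
    """
    fg = _lower(foreground)
    bg = _lower(background)
    sets = GeneSets(sets={"_set": ("set", frozenset(one_set))})
    row = enrich_sets(fg, bg, sets, alpha=alpha).iloc[0]
    fg_pct = round(100.0 * row["n_fg_in_set"] / row["n_fg"], 1) if row["n_fg"] else 0.0
    bg_pct = round(100.0 * row["n_bg_in_set"] / row["n_bg"], 1)
    return fg_pct, bg_pct, float(row["p_value"])
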