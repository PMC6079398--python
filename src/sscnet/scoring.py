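"""Per-gene scores: percentile ranks, fold change, change percentage and
the expression index.

The expression index weights *relative* expression change by *absolute*
abundance:

    index = avg_change_pct * avg_percentile

where ``avg_change_pct = 2|a - b| / (a + b)`` maps every fold change into
``[0, 2]`` (a gene expressed in only one condition scores exactly 2), and
``avg_percentile`` is the mean of the gene's within-condition abundance
percentile ranks.  Large fold changes at negligible abundance are thereby
down-weighted, while confident changes in abundant genes bubble up —
useful when each condition has a single profile and no replicate-based
p-value is possible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .expression import ExpressionTable

logger = logging.getLogger("sscnet.scoring")

#: change-percentage strategies, pluggable by name
ChangeStrategy = Callable[[float, float], float]


def percentile_ranks(values: Sequence[float]) -> np.ndarray:
    """Ascending percentile rank of each value, ties averaged.

    rank / N with tie-averaged ranks: the maximum maps to 1.0, and every
    percentile lies in (0, 1].  Order-preserving and invariant under any
    strictly increasing transform of the values (in particular under
    rescaling a whole condition by a positive constant).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("percentile_ranks requires a non-empty list")
    return stats.rankdata(arr, method="average") / arr.size


def change_percentage(a: float, b: float) -> float:
    """Symmetric relative difference 2|a - b| / (a + b), in [0, 2].

    0 iff a == b; exactly 2 iff exactly one of the two is 0 ("absent
    change").  Undefined when both are 0 (such genes are removed by the
    FPKM filter whenever min_fpkm > 0).
    """
    if a < 0 or b < 0:
        raise InputError(f"FPKM values must be non-negative, got ({a}, {b})")
    if a == 0 and b == 0:
        raise InputError("change_percentage undefined for a = b = 0")
    return 2.0 * abs(a - b) / (a + b)


def fold_change(a: float, b: float) -> tuple[float, str]:
    """Unsigned fold-change magnitude max/min plus a direction label.

    Returns ``(magnitude, direction)`` with magnitude >= 1 (``inf`` when
    the smaller value is 0) and direction ``up`` (a > b), ``down``
    (a < b) or ``flat``.
    """
    if a < 0 or b < 0:
        raise InputError(f"FPKM values must be non-negative, got ({a}, {b})")
    if a == 0 and b == 0:
        raise InputError("fold_change undefined for a = b = 0")
    lo, hi = min(a, b), max(a, b)
    magnitude = math.inf if lo == 0 else hi / lo
    direction = "up" if a > b else ("down" if a < b else "flat")
    return magnitude, direction


@dataclass(frozen=True)
class GeneScoreTable:
    """Scored genes, one row each.

    ``data`` columns: gene, fpkm_a, fpkm_b, percentile_a, percentile_b,
    avg_percentile, fold_change, direction, change_pct, expression_index.
    """

    data: pd.DataFrame
    condition_a_label: str = "condition_a"
    condition_b_label: str = "condition_b"

    def __len__(self) -> int:
        return len(self.data)

    def index_of(self, genes: Iterable[str]) -> pd.DataFrame:
        """Rows for the given genes, matched case-insensitively."""
        wanted = {g.strip().lower() for g in genes}
        return self.data[self.data["gene"].str.lower().isin(wanted)]

    def write(self, path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "GeneScoreTable":
        return cls(data=pd.read_csv(path, sep=sep))


def score_table(
    table: ExpressionTable,
    change_strategy: ChangeStrategy = change_percentage,
) -> GeneScoreTable:
    """Score every gene of a (quality-filtered) expression table.

    Percentiles are computed within each condition over the retained
    genes only, so the filtered universe defines the ranks.
    ``change_strategy`` defaults to the symmetric relative difference
    and may be swapped for any ``f(a, b) -> [0, 2]`` form.
    """
    df = table.data
    if df.empty:
        raise InputError("cannot score an empty expression table")
    if not df["gene"].str.lower().is_unique:
        raise InputError("gene ids must be unique before scoring; run collapse_duplicates")

    a = df["fpkm_a"].to_numpy(float)
    b = df["fpkm_b"].to_numpy(float)
    pa = percentile_ranks(a)
    pb = percentile_ranks(b)
    change = np.array([change_strategy(x, y) for x, y in zip(a, b)])
    fc = np.array([math.inf if min(x, y) == 0 else max(x, y) / min(x, y) for x, y in zip(a, b)])
    direction = np.where(a > b, "up", np.where(a < b, "down", "flat"))

    out = pd.DataFrame(
        {
            "gene": df["gene"].to_numpy(),
            "fpkm_a": a,
            "fpkm_b": b,
            "percentile_a": pa,
            "percentile_b": pb,
            "avg_percentile": (pa + pb) / 2.0,
            "fold_change": fc,
            "direction": direction,
            "change_pct": change,
        }
    )
    out["expression_index"] = out["change_pct"] * out["avg_percentile"]
    return GeneScoreTable(
        data=out,
        condition_a_label=table.condition_a_label,
        condition_b_label=table.condition_b_label,
    )


@dataclass(frozen=True)
class MarkerDiagnostics:
    """Abundance/fold-change diagnostics of a positive-reference set.

    ``pearson_r``/``p_value`` relate the abundance measure (average
    percentile by default) to fold-change magnitude across the markers
    found in the table; both are ``nan`` when fewer than 3 usable
    markers exist or the points are degenerate (zero variance).
    """

    n_found: int
    found: tuple[str, ...]
    missing: tuple[str, ...]
    pearson_r: float
    p_value: float
    fc_range: tuple[float, float]
    percentile_range: tuple[float, float]
    index_range: tuple[float, float]

    @property
    def computable(self) -> bool:
        return not math.isnan(self.pearson_r)


def marker_diagnostics(
    scores: GeneScoreTable,
    markers: Iterable[str],
    abundance: str = "percentile",
) -> MarkerDiagnostics:
    """Correlate marker abundance with fold change, as a data-quality check.

    In the biological regime this method targets, canonical markers are
    abundant but change modestly, so the correlation is expected to be
    negative.  ``abundance`` selects the x-variable: ``"percentile"``
    (average percentile rank, default) or ``"fpkm"`` (mean raw FPKM).
    Markers absent from the table are reported, not errors.  Markers
    with infinite fold change are unusable for the correlation.
    """
    if abundance not in ("percentile", "fpkm"):
        raise InputError(f"abundance must be 'percentile' or 'fpkm', got {abundance!r}")
    markers = list(markers)
    rows = scores.index_of(markers)
    found_keys = set(rows["gene"].str.lower())
    missing = tuple(m for m in markers if m.strip().lower() not in found_keys)

    usable = rows[np.isfinite(rows["fold_change"])]
    nan = float("nan")
    if len(rows) == 0:
        return MarkerDiagnostics(0, (), tuple(missing), nan, nan,
                                 (nan, nan), (nan, nan), (nan, nan))

    fc_range = (rows["fold_change"].min(), rows["fold_change"].max())
    pct_range = (rows["avg_percentile"].min(), rows["avg_percentile"].max())
    idx_range = (rows["expression_index"].min(), rows["expression_index"].max())

    r = p = nan
    if len(usable) < 3:
        logger.warning(
            "only %d markers with finite fold change found; correlation suppressed",
            len(usable),
        )
    else:
        x = (usable["avg_percentile"] if abundance == "percentile"
             else (usable["fpkm_a"] + usable["fpkm_b"]) / 2.0).to_numpy(float)
        y = usable["fold_change"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("marker correlation not computable: zero variance")
        else:
            r, p = stats.pearsonr(x, y)
    if missing:
        logger.warning("markers absent from score table: %s", ", ".join(missing))
    return MarkerDiagnostics(
        n_found=len(rows),
        found=tuple(rows["gene"]),
        missing=tuple(missing),
        pearson_r=float(r),
        p_value=float(p),
        fc_range=(float(fc_range[0]), float(fc_range[1])),
        percentile_range=(float(pct_range[0]), float(pct_range[1])),
        index_range=(float(idx_range[0]), float(idx_range[1])),
    )
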