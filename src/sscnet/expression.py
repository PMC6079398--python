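"""Reading, validation and quality filtering of two-condition FPKM tables.

The pipeline starts from a table with one abundance value (FPKM:
fragments per kilobase of exon model per million mapped fragments) per
gene per condition — no replicates.  Condition *a* is the state of
interest (e.g. primitive type A spermatogonia, mostly self-renewing
stem cells) and condition *b* the reference (type A spermatogonia,
mostly differentiating).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger("sscnet.expression")

#: canonical column names used internally and on output
COLUMNS = ("gene", "fpkm_a", "fpkm_b")


@dataclass(frozen=True)
class ExpressionTable:
    """A gene x 2-condition abundance table.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``gene`` (symbol), ``fpkm_a``, ``fpkm_b`` (non-negative
        floats, FPKM units).
    condition_a_label, condition_b_label : str
        Human-readable names of the two conditions; *a* is the
        condition of interest.
    """

    data: pd.DataFrame
    condition_a_label: str = "condition_a"
    condition_b_label: str = "condition_b"

    def __post_init__(self) -> None:
        if self.condition_a_label == self.condition_b_label:
            raise ConfigurationError("condition labels must be distinct")
        if not self.condition_a_label or not self.condition_b_label:
            raise ConfigurationError("condition labels must be non-empty")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> list[str]:
        return self.data["gene"].tolist()

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False)


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_fpkm_table(
    path: str | Path,
    gene_col: str = "gene",
    a_col: str = "fpkm_a",
    b_col: str = "fpkm_b",
    condition_a_label: str | None = None,
    condition_b_label: str | None = None,
    delimiter: str | None = None,
) -> ExpressionTable:
    """Parse a TSV/CSV FPKM table into an :class:`ExpressionTable`.

    The delimiter is inferred from the file extension (``.csv`` → comma,
    anything else → tab) unless given explicitly.  Gene symbols are
    whitespace-trimmed.  Non-numeric or negative FPKM values raise
    :class:`InputError` naming the offending gene and column; a missing
    or duplicated header column raises :class:`ConfigurationError`.
    Duplicate gene ids are retained here — resolve them with
    :func:`collapse_duplicates`.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"expression table {path} is empty") from None

    # pandas mangles duplicated header names to 'x', 'x.1'; detect them
    mangled = [c for c in raw.columns if "." in c and c.rsplit(".", 1)[-1].isdigit()]
    if mangled:
        raise ConfigurationError(
            f"duplicated header column(s) in {path}: {sorted(set(c.rsplit('.', 1)[0] for c in mangled))}"
        )
    for col in (gene_col, a_col, b_col):
        if col not in raw.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} (header: {list(raw.columns)})"
            )
    if raw.empty:
        raise InputError(f"expression table {path} has a header but no rows")

    genes = raw[gene_col].astype(str).str.strip()
    out = pd.DataFrame({"gene": genes})
    for name, col in (("fpkm_a", a_col), ("fpkm_b", b_col)):
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() | ~pd.Series(map(_finite, values), index=values.index)
        if bad.any():
            i = bad.idxmax()
            raise InputError(
                f"non-numeric FPKM value {raw[col][i]!r} for gene {genes[i]!r} "
                f"in column {col!r}"
            )
        if (values < 0).any():
            i = (values < 0).idxmax()
            raise InputError(
                f"negative FPKM value {values[i]} for gene {genes[i]!r} in column {col!r}"
            )
        out[name] = values.astype(float)

    return ExpressionTable(
        data=out.reset_index(drop=True),
        condition_a_label=condition_a_label or a_col,
        condition_b_label=condition_b_label or b_col,
    )


def _finite(x: float) -> bool:
    try:
        return x == x and x not in (float("inf"), float("-inf"))
    except TypeError:  # pragma: no cover
        return False


def collapse_duplicates(table: ExpressionTable) -> ExpressionTable:
    """Resolve case-insensitive duplicate gene symbols.

    For each symbol appearing more than once (compared case-insensitively)
    the record with the maximal ``fpkm_a + fpkm_b`` is kept — the dominant
    isoform/probe signal; ties keep the first record encountered.
    """
    df = table.data
    key = df["gene"].str.lower()
    if key.is_unique:
        return table
    total = df["fpkm_a"] + df["fpkm_b"]
    # stable: idxmax returns the first occurrence of the maximum
    keep = total.groupby(key, sort=False).idxmax()
    kept = df.loc[sorted(keep)].reset_index(drop=True)
    logger.info("collapsed %d duplicate records to %d genes", len(df) - len(kept), len(kept))
    return replace(table, data=kept)


def filter_low_quality(
    table: ExpressionTable,
    min_fpkm: float = 0.1,
    strictness: str = "either",
) -> ExpressionTable:
    """Drop genes not detected at ``min_fpkm`` FPKM.

    With ``strictness="either"`` (default) a gene is retained iff
    ``max(fpkm_a, fpkm_b) >= min_fpkm`` — genes expressed in only one
    condition survive, which is required for the on/off ("absent
    change") case downstream.  ``strictness="both"`` requires both
    conditions to pass.  Retained values are never modified.
    """
    if min_fpkm < 0:
        raise ConfigurationError(f"min_fpkm must be >= 0, got {min_fpkm}")
    if strictness not in ("either", "both"):
        raise ConfigurationError(f"strictness must be 'either' or 'both', got {strictness!r}")
    df = table.data
    if strictness == "either":
        mask = (df["fpkm_a"] >= min_fpkm) | (df["fpkm_b"] >= min_fpkm)
    else:
        mask = (df["fpkm_a"] >= min_fpkm) & (df["fpkm_b"] >= min_fpkm)
    kept = df[mask].reset_index(drop=True)
    logger.info(
        "FPKM filter (>= %g, %s): retained %d of %d genes",
        min_fpkm, strictness, len(kept), len(df),
    )
    if kept.empty:
        logger.warning("FPKM filter removed every gene")
    return replace(table, data=kept)
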