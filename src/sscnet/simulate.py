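"""Synthetic two-condition expression data with planted structure.

The generator emulates the statistical regime the prioritization method
assumes: heavy-tailed (log-normal) FPKM abundances; a handful of
"marker" genes placed at high abundance with modest fold changes whose
magnitude is negatively coupled to abundance (abundant markers change
the least); a larger block of co-expressed "signal" genes at mixed
abundance; null genes with multiplicative noise only; and a fraction of
on/off genes expressed in one condition alone.  A companion interaction
generator plants a dense module over the marker and signal genes inside
an Erdős–Rényi background, and a gene-set generator emits a true
function set, a phenotype set and size-matched decoys.  Everything is
reproducible from a single seed and writable to the same on-disk
formats real inputs use (FPKM TSV, edge TSV, GMT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSets
from .errors import InputError
from .expression import ExpressionTable
from .network import EdgeList

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_expression",
    "simulate_interactions",
    "simulate_gene_sets",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults model a transcriptome-scale screen: 1000 genes of which 8
    are canonical-marker analogues (high abundance, fold change 1.25 to
    2.86 — modest, like real self-renewal markers) and 50 are signal
    genes with clearer fold changes at mixed abundance.
    """

    n_genes: int = 1000
    n_markers: int = 8
    n_signal: int = 50
    marker_abundance_quantile: float = 0.85  # markers drawn above this abundance quantile
    marker_fc_range: tuple[float, float] = (1.25, 2.86)
    signal_abundance_range: tuple[float, float] = (0.35, 0.95)  # abundance quantiles
    signal_fc_range: tuple[float, float] = (2.5, 6.0)
    null_fc_sd: float = 0.10        # sd of log-normal multiplicative noise on null genes
    dropout_rate: float = 0.02      # fraction of null genes expressed in one condition only
    seed: int = 0
    edge_density: float = 0.004     # Erdős–Rényi background density
    module_density: float = 0.35    # density of the planted module over marker ∪ signal

    def validate(self) -> None:
        if self.n_markers + self.n_signal > self.n_genes:
            raise InputError("n_markers + n_signal exceeds n_genes")
        for lo, hi in (self.marker_fc_range, self.signal_fc_range):
            if lo < 1 or hi < lo:
                raise InputError("fold-change ranges must satisfy 1 <= low <= high")
        if not (0 <= self.dropout_rate < 1):
            raise InputError("dropout_rate must be in [0, 1)")
        if not (0 < self.marker_abundance_quantile < 1):
            raise InputError("marker_abundance_quantile must be in (0, 1)")
        lo, hi = self.signal_abundance_range
        if not (0 <= lo <= hi < 1):
            raise InputError("signal_abundance_range must satisfy 0 <= low <= high < 1")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulation: which gene is what."""

    marker_ids: frozenset[str]
    signal_ids: frozenset[str]
    null_ids: frozenset[str]
    planted_module_edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def positives(self) -> frozenset[str]:
        return self.marker_ids | self.signal_ids


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionTable, SimTruth]:
    """Draw a synthetic two-condition FPKM table plus its ground truth.

    Baseline abundances are log-normal (heavy right tail, like FPKM).
    Markers sit above ``marker_abundance_quantile`` with fold changes in
    ``marker_fc_range`` assigned anti-rank to abundance (most abundant
    marker gets the smallest fold change), reproducing the negative
    abundance–fold-change correlation seen for real self-renewal
    markers; markers are upregulated in condition a.  Signal genes take
    fold changes in ``signal_fc_range`` at moderate-to-high abundance
    (``signal_abundance_range`` quantiles) and random direction.  Null
    genes get multiplicative log-normal noise only; a
    ``dropout_rate`` fraction of them is zeroed in one random condition.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    names = _gene_names(n)

    # log-normal baseline; sigma ~1.5 gives a realistic dynamic range
    base = rng.lognormal(mean=1.0, sigma=1.5, size=n)
    base = np.maximum(base, 0.2)  # keep every simulated gene above the 0.1 detect limit

    ids = rng.permutation(n)
    marker_pos = ids[: cfg.n_markers]
    signal_pos = ids[cfg.n_markers : cfg.n_markers + cfg.n_signal]
    null_pos = ids[cfg.n_markers + cfg.n_signal :]

    # markers: high-abundance baseline, modest FC anti-ranked to abundance
    q = rng.uniform(cfg.marker_abundance_quantile, 0.999, size=cfg.n_markers)
    marker_base = np.quantile(base, q)
    marker_fc = rng.uniform(*cfg.marker_fc_range, size=cfg.n_markers)
    order = np.argsort(np.argsort(marker_base))      # rank of each marker's abundance
    marker_fc = np.sort(marker_fc)[::-1][order]      # abundant -> small fold change

    a = base.copy()
    b = base.copy()
    b[marker_pos] = marker_base
    a[marker_pos] = marker_base * marker_fc          # markers up in condition a

    # signal genes: co-expressed with the markers, so moderately-to-highly
    # abundant, with clear fold changes in either direction
    sig_base = np.quantile(base, rng.uniform(*cfg.signal_abundance_range, size=cfg.n_signal))
    sig_fc = rng.uniform(*cfg.signal_fc_range, size=cfg.n_signal)
    sig_up = rng.random(cfg.n_signal) < 0.5
    a[signal_pos] = np.where(sig_up, sig_base * sig_fc, sig_base)
    b[signal_pos] = np.where(sig_up, sig_base, sig_base * sig_fc)

    noise_a = rng.lognormal(0.0, cfg.null_fc_sd, size=null_pos.size)
    noise_b = rng.lognormal(0.0, cfg.null_fc_sd, size=null_pos.size)
    a[null_pos] = base[null_pos] * noise_a
    b[null_pos] = base[null_pos] * noise_b

    n_drop = int(round(cfg.dropout_rate * null_pos.size))
    if n_drop:
        drop = rng.choice(null_pos, size=n_drop, replace=False)
        side = rng.random(n_drop) < 0.5
        a[drop[side]] = 0.0
        b[drop[~side]] = 0.0

    table = ExpressionTable(
        data=pd.DataFrame({"gene": names, "fpkm_a": a, "fpkm_b": b}),
        condition_a_label="self_renewing",
        condition_b_label="differentiating",
    )
    truth = SimTruth(
        marker_ids=frozenset(names[i] for i in marker_pos),
        signal_ids=frozenset(names[i] for i in signal_pos),
        null_ids=frozenset(names[i] for i in null_pos),
    )
    return table, truth


def simulate_interactions(
    truth: SimTruth, cfg: SimConfig
) -> tuple[EdgeList, SimTruth]:
    """Random interaction graph with a planted dense module.

    Erdős–Rényi background over all genes at ``edge_density`` with
    confidence scores uniform on [0.4, 1.0], plus a denser module
    (``module_density``) over marker ∪ signal genes scored uniform on
    [0.7, 1.0] — module edges always clear a 0.7 high-confidence
    filter.  Returns the edge list (unfiltered; scores in [0, 1]) and a
    copy of the truth carrying the planted module edges.
    """
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31) + 1)
    genes = sorted(truth.marker_ids | truth.signal_ids | truth.null_ids)
    module = sorted(truth.positives)

    def sampled_pairs(items: list[str], density: float) -> list[tuple[str, str]]:
        k = len(items)
        if k < 2 or density <= 0:
            return []
        iu = np.triu_indices(k, 1)
        hit = rng.random(iu[0].size) < density
        return [(items[i], items[j]) for i, j in zip(iu[0][hit], iu[1][hit])]

    rows: dict[tuple[str, str], float] = {}
    for u, v in sampled_pairs(genes, cfg.edge_density):
        rows[(u, v)] = rng.uniform(0.4, 1.0)
    module_edges = set()
    for u, v in sampled_pairs(module, cfg.module_density):
        rows[(u, v)] = rng.uniform(0.7, 1.0)  # module score overrides background
        module_edges.add((u, v))

    df = pd.DataFrame(
        [(u, v, s) for (u, v), s in rows.items()],
        columns=["gene_u", "gene_v", "score"],
    )
    edge_list = EdgeList(edges=df, score_threshold=0.0)
    truth_out = SimTruth(
        marker_ids=truth.marker_ids,
        signal_ids=truth.signal_ids,
        null_ids=truth.null_ids,
        planted_module_edges=frozenset(module_edges),
    )
    return edge_list, truth_out


def simulate_gene_sets(
    truth: SimTruth, n_decoy_sets: int = 10, seed: int = 0
) -> GeneSets:
    """Annotation sets for the simulated genes.

    ``true_function`` = marker ∪ signal (the proliferation/
    differentiation analogue); ``phenotype`` = a random half of it (the
    fertility-phenotype analogue); plus ``n_decoy_sets`` size-matched
    sets of random genes carrying no signal.
    """
    rng = np.random.default_rng(seed)
    positives = sorted(truth.positives)
    all_genes = sorted(truth.marker_ids | truth.signal_ids | truth.null_ids)

    pheno = sorted(rng.choice(positives, size=len(positives) // 2, replace=False))
    sets = {
        "true_function": ("planted proliferation/differentiation set", frozenset(positives)),
        "phenotype": ("planted fertility-phenotype set", frozenset(pheno)),
    }
    for i in range(n_decoy_sets):
        decoy = rng.choice(all_genes, size=len(positives), replace=False)
        sets[f"decoy_{i:02d}"] = (f"random decoy set {i}", frozenset(decoy))
    return GeneSets(sets=sets)
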