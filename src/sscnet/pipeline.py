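"""End-to-end orchestration: filter → score → scan → select → network →
annotate → enrich, with a YAML config, per-stage logging and a
reproducibility manifest.

Stages degrade gracefully: without an edge list the network and
enrichment stages are skipped (with an explicit notice) while the
earlier outputs are still produced.  Identical config + inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .cutoff import inclusive_cutoff, optimal_cutoff, scan_cutoffs, select_candidates
from .enrichment import enrich_sets, read_gmt
from .errors import ConfigurationError, InputError
from .expression import collapse_duplicates, filter_low_quality, read_fpkm_table
from .network import annotate_nodes, export_network, induce_refined_network, read_interactions
from .scoring import marker_diagnostics, score_table

logger = logging.getLogger("sscnet.pipeline")


@dataclass
class RunConfig:
    """All paths and parameters of one pipeline run.

    Defaults are the method's standard constants: FPKM detection limit
    0.1, scan step 0.001, interaction confidence 0.7, significance 0.05.
    """

    expression: str = ""
    positives: str = ""                 # text file, one gene symbol per line
    edges: str | None = None            # optional STRING-style TSV
    gene_sets: str | None = None        # optional GMT
    function_set_id: str | None = None  # set flagged as proliferation/differentiation
    phenotype_set_id: str | None = None # set flagged as fertility phenotype
    gene_col: str = "gene"
    a_col: str = "fpkm_a"
    b_col: str = "fpkm_b"
    min_fpkm: float = 0.1
    filter_strictness: str = "either"   # 'either' | 'both'
    step: float = 0.001
    edge_threshold: float = 0.7
    alpha: float = 0.05
    abundance_measure: str = "percentile"  # marker diagnostics x-variable
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} must be a YAML mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blanks and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    if not out:
        raise InputError(f"gene list {path} is empty")
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full prioritization pipeline; returns the summary dict.

    Writes every intermediate table under ``out_dir`` plus
    ``summary.json`` (counts, cutoffs, p-values) and ``manifest.json``
    (config hash, package and library versions).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.expression:
        raise ConfigurationError("config is missing the expression table path")
    if not cfg.positives:
        raise ConfigurationError("config is missing the positive-reference gene list")
    summary: dict = {"conditions": {}, "stages": {}}

    def stage(name):
        logger.info("stage %s: starting", name)
        return name

    # --- filter ---------------------------------------------------------
    s = stage("filter")
    try:
        table = read_fpkm_table(cfg.expression, cfg.gene_col, cfg.a_col, cfg.b_col)
        table = collapse_duplicates(table)
        n_input = len(table)
        table = filter_low_quality(table, cfg.min_fpkm, cfg.filter_strictness)
    except Exception as e:
        raise type(e)(f"[stage {s}] {e} (check the expression table and column names)") from e
    summary["conditions"] = {"a": table.condition_a_label, "b": table.condition_b_label}
    summary["stages"][s] = {"n_genes_input": n_input, "n_genes_retained": len(table)}
    table.write(out / "filtered.tsv")

    # --- score ----------------------------------------------------------
    s = stage("score")
    scores = score_table(table)
    positives = read_gene_list(cfg.positives)
    diag = marker_diagnostics(scores, positives, abundance=cfg.abundance_measure)
    summary["stages"][s] = {
        "n_scored": len(scores),
        "markers": {
            "n_found": diag.n_found,
            "missing": list(diag.missing),
            "pearson_r": _num(diag.pearson_r),
            "p_value": _num(diag.p_value),
            "fold_change_range": [_num(x) for x in diag.fc_range],
            "percentile_range": [_num(x) for x in diag.percentile_range],
            "index_range": [_num(x) for x in diag.index_range],
        },
    }
    scores.write(out / "scores.tsv")

    # --- scan -----------------------------------------------------------
    s = stage("scan")
    scan = scan_cutoffs(scores, positives, step=cfg.step)
    best = optimal_cutoff(scan, alpha=cfg.alpha)
    inclusive = inclusive_cutoff(scores, positives, step=cfg.step, alpha=cfg.alpha)
    candidates = select_candidates(scores, best.cutoff)
    scan.write(out / "scan.tsv")
    (out / "candidates.txt").write_text("".join(g + "\n" for g in candidates))
    summary["stages"][s] = {
        "optimal": best.as_dict(),
        "inclusive": inclusive.as_dict(),
        "n_candidates": len(candidates),
    }

    # --- network --------------------------------------------------------
    function_set: list[str] = []
    phenotype_set: list[str] = []
    gene_sets = None
    if cfg.gene_sets:
        gene_sets = read_gmt(cfg.gene_sets)
        if cfg.function_set_id:
            function_set = sorted(gene_sets.members(cfg.function_set_id))
        if cfg.phenotype_set_id:
            phenotype_set = sorted(gene_sets.members(cfg.phenotype_set_id))

    net = None
    if cfg.edges:
        s = stage("network")
        edge_list = read_interactions(cfg.edges, threshold=cfg.edge_threshold)
        net = induce_refined_network(candidates, edge_list)
        net = annotate_nodes(net, scores, function_set, phenotype_set, positives)
        export_network(net, out / "network")
        summary["stages"][s] = net.summary()
    else:
        logger.warning("no edge list configured: network stage skipped")
        summary["stages"]["network"] = {"skipped": "no edge list configured"}

    # --- enrich ---------------------------------------------------------
    if gene_sets is not None:
        s = stage("enrich")
        foreground = sorted(n for n in net.graph.nodes) if net is not None else candidates
        background = scores.data["gene"].tolist()
        enr = enrich_sets(foreground, background, gene_sets, alpha=cfg.alpha)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["stages"][s] = {
            "n_sets": len(enr),
            "n_significant": int(enr["significant"].sum()),
            "top_set": enr.iloc[0]["set_id"] if len(enr) else None,
            "top_p": _num(enr.iloc[0]["p_value"]) if len(enr) else None,
        }
    else:
        logger.warning("no gene sets configured: enrichment stage skipped")
        summary["stages"]["enrich"] = {"skipped": "no gene sets configured"}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "config": asdict(cfg),
        "config_sha256": cfg.digest(),
        "sscnet_version": __version__,
        "library_versions": _library_versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _num(x) -> float | None:
    """JSON-safe number: NaN/inf become None."""
    import math

    x = float(x)
    return x if math.isfinite(x) else None


def _library_versions() -> dict[str, str]:
    import networkx
    import numpy
    import pandas
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
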