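"""Interaction-based refinement of the candidate list.

Candidates are intersected with a high-confidence protein–protein
interaction edge list (STRING-style; combined score >= 0.7 by default):
only edges with both endpoints among the candidates are kept and
isolated candidates are dropped.  The surviving genes form the
"refined network", each node annotated with its expression direction,
abundance (average percentile), relative change, and membership flags
for function / phenotype / marker gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import InputError
from .scoring import GeneScoreTable

logger = logging.getLogger("sscnet.network")

NODE_ATTRS = ("direction", "avg_percentile", "change_pct",
              "proliferation_differentiation", "fertility_phenotype", "canonical_marker")


@dataclass(frozen=True)
class EdgeList:
    """Undirected, deduplicated, scored interaction edges.

    ``edges`` columns: gene_u, gene_v, score (floats in [0, 1]).  After
    :func:`read_interactions` all retained scores are >= the threshold,
    self-loops are gone and each unordered pair occurs once (max score).
    """

    edges: pd.DataFrame
    score_threshold: float = 0.7

    def __len__(self) -> int:
        return len(self.edges)

    def write(self, path, sep: str = "\t") -> None:
        self.edges.to_csv(path, sep=sep, index=False)


def _dedupe_edges(df: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops; merge (u,v)/(v,u) duplicates keeping the max score."""
    df = df[df["gene_u"].str.lower() != df["gene_v"].str.lower()]
    key = df.apply(
        lambda r: tuple(sorted((r["gene_u"].lower(), r["gene_v"].lower()))), axis=1
    )
    df = df.assign(_key=key)
    # stable: first occurrence of the max score per pair keeps its orientation
    idx = df.groupby("_key", sort=False)["score"].idxmax()
    return df.loc[sorted(idx)].drop(columns="_key").reset_index(drop=True)


def read_interactions(
    path: str | Path,
    threshold: float = 0.7,
    u_col: str | int = 0,
    v_col: str | int = 1,
    score_col: str | int = 2,
    id_map: dict[str, str] | None = None,
) -> EdgeList:
    """Read a STRING-style TSV edge list and keep high-confidence edges.

    Score dialect is auto-detected: if any score exceeds 1 the file is
    taken to use STRING's 0–999 integer combined scores and every score
    is divided by 1000; otherwise scores are used as-is (0–1 fractions).
    The threshold is applied *after* rescaling, inclusively (>=).
    Malformed rows are skipped with a counted warning; a file whose rows
    are all malformed is an input error.  ``id_map`` optionally
    translates protein ids to gene symbols (unmapped ids pass through).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise InputError(f"interaction file {path} is empty") from None

    def col(c):
        return raw.columns[c] if isinstance(c, int) else c

    try:
        u = raw[col(u_col)].astype(str).str.strip()
        v = raw[col(v_col)].astype(str).str.strip()
        score = pd.to_numeric(raw[col(score_col)], errors="coerce")
    except (KeyError, IndexError) as e:
        raise InputError(f"interaction file {path}: cannot locate columns: {e}") from None

    bad = score.isna() | u.eq("") | v.eq("")
    if bad.all():
        raise InputError(f"interaction file {path}: every row is malformed")
    if bad.any():
        logger.warning("skipped %d malformed interaction row(s)", int(bad.sum()))
    df = pd.DataFrame({"gene_u": u[~bad], "gene_v": v[~bad], "score": score[~bad].astype(float)})

    if (df["score"] > 1).any():  # STRING 0–999 integer dialect
        df["score"] = df["score"] / 1000.0
    if id_map:
        lower_map = {k.lower(): v for k, v in id_map.items()}
        for c in ("gene_u", "gene_v"):
            df[c] = df[c].map(lambda g: lower_map.get(g.lower(), g))

    df = df[df["score"] >= threshold]
    df = _dedupe_edges(df.reset_index(drop=True))
    logger.info("loaded %d high-confidence edges (score >= %g)", len(df), threshold)
    return EdgeList(edges=df, score_threshold=threshold)


@dataclass
class AnnotatedNetwork:
    """The refined expression–function network.

    Wraps an undirected simple :class:`networkx.Graph`.  Node attributes
    (present after :func:`annotate_nodes`): ``direction`` (up/down/flat),
    ``avg_percentile`` (absolute expression level), ``change_pct``
    (relative change) and three boolean flags.  Edge attribute:
    ``score``.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> dict:
        """Counts and 1-decimal percentages over the node annotations."""
        n = self.n_nodes
        counts = {"n_nodes": n, "n_edges": self.n_edges}
        if n and "direction" in next(iter(self.graph.nodes(data=True)))[1]:
            for d in ("up", "down", "flat"):
                counts[f"n_{d}"] = sum(
                    1 for _, a in self.graph.nodes(data=True) if a["direction"] == d
                )
            for flag in ("proliferation_differentiation", "fertility_phenotype",
                         "canonical_marker"):
                k = sum(1 for _, a in self.graph.nodes(data=True) if a.get(flag))
                counts[f"n_{flag}"] = k
                counts[f"pct_{flag}"] = round(100.0 * k / n, 1)
        return counts


def induce_refined_network(
    candidates: Iterable[str], edges: EdgeList
) -> AnnotatedNetwork:
    """Induced subgraph of the edge list over the candidate genes.

    Keeps only edges with both endpoints among the candidates (matched
    case-insensitively; node names take the candidate spelling) and
    drops candidates without any retained interaction.
    """
    candidates = list(candidates)
    if not candidates:
        raise InputError("candidate list is empty")
    by_key = {c.strip().lower(): c for c in candidates}

    g = nx.Graph()
    for _, row in edges.edges.iterrows():
        ku, kv = row["gene_u"].lower(), row["gene_v"].lower()
        if ku in by_key and kv in by_key:
            u, v = by_key[ku], by_key[kv]
            s = float(row["score"])
            if g.has_edge(u, v):
                g[u][v]["score"] = max(g[u][v]["score"], s)
            else:
                g.add_edge(u, v, score=s)
    if g.number_of_nodes() == 0:
        logger.warning("refined network is empty: no interactions among candidates")
    logger.info(
        "refined network: %d of %d candidates, %d edges",
        g.number_of_nodes(), len(candidates), g.number_of_edges(),
    )
    return AnnotatedNetwork(graph=g)


def annotate_nodes(
    net: AnnotatedNetwork,
    scores: GeneScoreTable,
    function_set: Iterable[str] = (),
    phenotype_set: Iterable[str] = (),
    markers: Iterable[str] = (),
) -> AnnotatedNetwork:
    """Attach expression and gene-set annotations to every node.

    Direction comes from the sign of fpkm_a − fpkm_b; abundance
    (avg_percentile) and relative change (change_pct) are copied from
    the score table; the three flags record membership of the function,
    phenotype and marker sets (non-exclusive).  A node missing from the
    score table is an internal consistency error.
    """
    df = scores.data.set_index(scores.data["gene"].str.lower())
    fset = {g.strip().lower() for g in function_set}
    pset = {g.strip().lower() for g in phenotype_set}
    mset = {g.strip().lower() for g in markers}

    for node in net.graph.nodes:
        key = node.lower()
        if key not in df.index:
            raise InputError(f"network node {node!r} missing from the score table")
        row = df.loc[key]
        net.graph.nodes[node].update(
            direction=("up" if row["fpkm_a"] > row["fpkm_b"]
                       else "down" if row["fpkm_a"] < row["fpkm_b"] else "flat"),
            avg_percentile=float(row["avg_percentile"]),
            change_pct=float(row["change_pct"]),
            proliferation_differentiation=key in fset,
            fertility_phenotype=key in pset,
            canonical_marker=key in mset,
        )
    return net


def ego_subnetwork(
    net: AnnotatedNetwork, center: str, radius: int = 2
) -> AnnotatedNetwork:
    """Induced subgraph of nodes within graph distance <= radius of
    ``center`` (annotations preserved)."""
    match = [n for n in net.graph.nodes if n.lower() == center.strip().lower()]
    if not match:
        raise InputError(f"center gene {center!r} is not a network node")
    sub = nx.ego_graph(net.graph, match[0], radius=radius)
    return AnnotatedNetwork(graph=sub)


def export_network(net: AnnotatedNetwork, prefix: str | Path) -> dict[str, Path]:
    """Write node TSV, SIF-compatible edge TSV and GraphML.

    Files are ``<prefix>_nodes.tsv``, ``<prefix>_edges.tsv`` (columns
    gene_u, interaction, gene_v, score) and ``<prefix>.graphml``; the
    GraphML round-trips losslessly through :func:`read_graphml`.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": prefix.parent / (prefix.name + "_nodes.tsv"),
        "edges": prefix.parent / (prefix.name + "_edges.tsv"),
        "graphml": prefix.parent / (prefix.name + ".graphml"),
    }

    node_rows = [
        {"gene": n, **{k: a.get(k, "") for k in NODE_ATTRS}}
        for n, a in net.graph.nodes(data=True)
    ]
    pd.DataFrame(node_rows, columns=["gene", *NODE_ATTRS]).to_csv(
        paths["nodes"], sep="\t", index=False
    )
    edge_rows = [
        {"gene_u": u, "interaction": "pp", "gene_v": v, "score": a.get("score", "")}
        for u, v, a in net.graph.edges(data=True)
    ]
    pd.DataFrame(edge_rows, columns=["gene_u", "interaction", "gene_v", "score"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    nx.write_graphml(net.graph, paths["graphml"], named_key_ids=True)
    return paths


def read_graphml(path: str | Path) -> AnnotatedNetwork:
    """Read a network previously written by :func:`export_network`."""
    return AnnotatedNetwork(graph=nx.read_graphml(Path(path)))
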