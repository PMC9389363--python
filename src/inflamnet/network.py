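"""Negative-positive (NP) protein-interaction network and interface genes.

The core procedure: take high-confidence protein-protein interactions
(combined score strictly above 900), restrict them to the genes of two
disease modules, keep only edges whose expression Pearson correlation exceeds
0.22 in absolute value (strict), and annotate each surviving edge with its
correlation sign (positive/negative) and scope (intra- vs cross-module).
Genes bound to a gene of the *other* module — genes with at least one
cross-module edge — are the interface genes, the inflammation-cancer
interface.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .modules import ModuleDefinition

logger = logging.getLogger(__name__)

CONFIDENCE_THRESHOLD = 900
R_THRESHOLD = 0.22
UNSCORED_CONFIDENCE = 1000


def load_interactions(
    paths: list, confidence_threshold: int = CONFIDENCE_THRESHOLD
) -> pd.DataFrame:
    """Read STRING-style edge lists, filter by confidence, deduplicate.

    Each file is a TSV of ``protein1 protein2 combined_score`` (a header row
    is detected and skipped) or an unscored two-column pair list; unscored
    edges get confidence 1000 so curated sources pass the filter.  Gene names
    are uppercased, self-loops dropped, pairs canonicalized (sorted) and
    deduplicated keeping the maximum confidence.  Only edges with confidence
    strictly greater than ``confidence_threshold`` are retained.
    """
    rows = []
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    parts = line.split()
                if len(parts) not in (2, 3):
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                    )
                if len(parts) == 3:
                    try:
                        score = float(parts[2])
                    except ValueError:
                        if lineno == 1:  # header
                            continue
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric confidence {parts[2]!r}"
                        ) from None
                else:
                    score = UNSCORED_CONFIDENCE
                a, b = parts[0].upper(), parts[1].upper()
                if a == b:
                    continue
                if a > b:
                    a, b = b, a
                rows.append((a, b, score, str(path)))
    table = pd.DataFrame(rows, columns=["gene1", "gene2", "confidence", "source"])
    if len(table):
        table = (
            table.sort_values("confidence")
            .groupby(["gene1", "gene2"], as_index=False)
            .last()
        )
        table = table[table["confidence"] > confidence_threshold].reset_index(
            drop=True
        )
    return table


def build_np_network(
    interactions: pd.DataFrame,
    module_a: ModuleDefinition,
    module_b: ModuleDefinition,
    expr: pd.DataFrame,
    correlation_samples: list[str] | None = None,
    r_threshold: float = R_THRESHOLD,
) -> nx.Graph:
    """Correlation-filter the interactome restricted to two modules' genes.

    Nodes are module genes present in both the interaction table and the
    expression matrix, annotated with their module.  For each interaction
    among them, the Pearson r over ``correlation_samples`` (default: all
    samples of ``expr``) is computed; the edge survives iff |r| > r_threshold
    (strict), annotated with r, sign and scope in {intra, cross}.  Edges of
    constant-expression genes are dropped with a warning.
    """
    genes_a, genes_b = set(module_a.genes), set(module_b.genes)
    if genes_a & genes_b:
        raise ValueError("module gene sets must be disjoint")
    if correlation_samples is None:
        correlation_samples = list(expr.columns)
    if len(correlation_samples) < 3:
        raise ValueError("need at least 3 samples to compute correlations")

    module_of = {g: module_a.name for g in genes_a}
    module_of.update({g: module_b.name for g in genes_b})
    in_interactome = set(interactions["gene1"]) | set(interactions["gene2"])
    nodes = (genes_a | genes_b) & in_interactome & set(expr.index)
    if not nodes:
        raise ValueError("no module genes present in both interactome and expression")
    dropped_unmapped = len((genes_a | genes_b) - nodes)
    if dropped_unmapped:
        logger.info(
            "%d module genes absent from interactome or expression", dropped_unmapped
        )

    sub = expr.loc[sorted(nodes), correlation_samples].to_numpy(dtype=float)
    gene_idx = {g: i for i, g in enumerate(sorted(nodes))}
    sd = sub.std(axis=1)
    centered = sub - sub.mean(axis=1, keepdims=True)

    graph = nx.Graph()
    graph.graph["module_a"] = module_a.name
    graph.graph["module_b"] = module_b.name
    graph.graph["r_threshold"] = r_threshold
    for g in sorted(nodes):
        graph.add_node(g, module=module_of[g])

    n_const = 0
    for _, row in interactions.iterrows():
        a, b = row["gene1"], row["gene2"]
        if a not in gene_idx or b not in gene_idx:
            continue
        ia, ib = gene_idx[a], gene_idx[b]
        if sd[ia] == 0 or sd[ib] == 0:
            n_const += 1
            continue
        r = float(
            centered[ia] @ centered[ib] / (len(correlation_samples) * sd[ia] * sd[ib])
        )
        if abs(r) > r_threshold:
            graph.add_edge(
                a,
                b,
                r=r,
                confidence=float(row["confidence"]),
                sign="positive" if r > 0 else "negative",
                scope="intra" if module_of[a] == module_of[b] else "cross",
            )
    if n_const:
        logger.warning("dropped %d edges touching constant-expression genes", n_const)
    return graph


def extract_interface_genes(
    network: nx.Graph,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interface genes of each module: genes with >= 1 cross-module edge.

    Returns one table per module (gene, cross_edges), sorted by descending
    cross-edge count then gene name.
    """
    counts: dict[str, int] = {}
    for a, b, data in network.edges(data=True):
        if data["scope"] == "cross":
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
    out = []
    for mod in (network.graph["module_a"], network.graph["module_b"]):
        rows = [
            (g, counts[g])
            for g in counts
            if network.nodes[g]["module"] == mod
        ]
        table = pd.DataFrame(rows, columns=["gene", "cross_edges"])
        table = table.sort_values(
            ["cross_edges", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
        out.append(table)
    return out[0], out[1]


def neighborhood(
    network: nx.Graph, seed_genes: list[str], order: int = 1
) -> nx.Graph:
    """Induced subgraph on seed genes plus all nodes within ``order`` hops."""
    if order < 1:
        raise ValueError("order must be >= 1")
    present = [g for g in seed_genes if g in network]
    for g in seed_genes:
        if g not in network:
            logger.warning("seed gene %s absent from network; skipped", g)
    keep = set(present)
    for g in present:
        keep.update(
            nx.single_source_shortest_path_length(network, g, cutoff=order)
        )
    return network.subgraph(keep).copy()


def network_to_edge_table(network: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "gene1": min(a, b),
            "gene2": max(a, b),
            "confidence": d["confidence"],
            "r": d["r"],
            "sign": d["sign"],
            "scope": d["scope"],
        }
        for a, b, d in network.edges(data=True)
    ]
    return pd.DataFrame(
        rows, columns=["gene1", "gene2", "confidence", "r", "sign", "scope"]
    ).sort_values(["gene1", "gene2"]).reset_index(drop=True)
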