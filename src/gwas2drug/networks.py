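"""Protein-protein interaction network metrics and subnetwork extraction.

Consumes STRING-style weighted edge lists (combined_score in [0, 1000]).
Node metrics follow the percentage conventions: normalized degree is
100 * deg / (n-1) (percent of possible neighbors) and normalized betweenness
is 100 * 2B / ((n-1)(n-2)) for undirected unweighted shortest paths (percent
of maximum pair coverage).  Also classifies significant genes against
genome-wide significant loci with the 35/10 kb regulatory window and the
symmetric 500 kb LD window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NodeMetrics",
    "read_string_edges",
    "node_metrics",
    "layout_fr",
    "class_target_subgraph",
    "pathway_core_subgraph",
    "classify_genes_vs_loci",
]


@dataclass
class NodeMetrics:
    gene_id: str
    degree_norm: float       # percent of possible neighbors
    betweenness_norm: float  # percent of maximum pair coverage
    neglog10p: float = np.nan
    hub_degree: bool = False
    hub_betweenness: bool = False


def read_string_edges(path, min_score: float = 0.0) -> nx.Graph:
    """Read a STRING-style TSV (protein1, protein2, combined_score) into an
    undirected weighted graph, dropping self-loops and low-score edges."""
    return read_string_edges_df(pd.read_csv(path, sep="\t"), min_score)


def read_string_edges_df(df: pd.DataFrame, min_score: float = 0.0) -> nx.Graph:
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    G = nx.Graph()
    for p1, p2, s in df[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        if p1 == p2 or s < min_score:
            continue
        G.add_edge(str(p1), str(p2), weight=float(s))
    return G


def node_metrics(
    graph: nx.Graph,
    min_score: float = 0.0,
    neglog10p: dict[str, float] | None = None,
    hub_degree_pct: float = 5.0,
    hub_betweenness_pct: float = 2.5,
) -> list[NodeMetrics]:
    """Normalized degree and betweenness percentages per gene.

    Edges with weight below ``min_score`` are dropped first; nodes are kept.
    Hub flags mark genes above the configurable percentage thresholds.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    G = nx.Graph()
    G.add_nodes_from(graph.nodes)
    G.add_edges_from(
        (u, v) for u, v, d in graph.edges(data=True) if d.get("weight", 0.0) >= min_score
    )
    n = G.number_of_nodes()
    if n > 2:
        btw = nx.betweenness_centrality(G, normalized=True)  # divides by (n-1)(n-2)/2
    else:
        warnings.warn("fewer than 3 nodes: betweenness reported as 0")
        btw = {v: 0.0 for v in G}
    out = []
    for v in G.nodes:
        deg_pct = 100.0 * G.degree(v) / (n - 1) if n > 1 else 0.0
        btw_pct = 100.0 * btw[v]
        out.append(
            NodeMetrics(
                gene_id=v,
                degree_norm=deg_pct,
                betweenness_norm=btw_pct,
                neglog10p=(neglog10p or {}).get(v, np.nan),
                hub_degree=deg_pct > hub_degree_pct,
                hub_betweenness=btw_pct > hub_betweenness_pct,
            )
        )
    return out


def layout_fr(graph: nx.Graph, seed: int = 0, iterations: int = 200) -> dict[str, np.ndarray]:
    """Fruchterman-Reingold force-directed positions, deterministic under seed."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): np.zeros(2)}
    return nx.spring_layout(graph, seed=seed, iterations=iterations)


def class_target_subgraph(
    graph: nx.Graph, drug_sets_in_class: dict[str, set[str]], min_drugs: int = 2
) -> nx.Graph:
    """Induced subgraph on genes targeted by >= min_drugs distinct drugs of
    the class (the Fig.-style 'targeted by at least 2 drugs' rule)."""
    if not drug_sets_in_class:
        raise ValueError("class has no drugs")
    counts: dict[str, int] = {}
    for genes in drug_sets_in_class.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    keep = {g for g, c in counts.items() if c >= min_drugs}
    sub = graph.subgraph(keep & set(graph.nodes)).copy()
    for g in keep - set(graph.nodes):
        sub.add_node(g)
    if sub.number_of_nodes() == 0:
        warnings.warn("no gene targeted by enough drugs: empty subgraph")
    return sub


def pathway_core_subgraph(
    graph: nx.Graph, pathway_sets: dict[str, set[str]], min_pathways: int = 10
) -> nx.Graph:
    """Induced subgraph on genes present in >= min_pathways pathway sets."""
    if not pathway_sets:
        raise ValueError("pathway collection is empty")
    counts: dict[str, int] = {}
    for genes in pathway_sets.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    keep = {g for g, c in counts.items() if c >= min_pathways}
    sub = graph.subgraph(keep & set(graph.nodes)).copy()
    for g in keep - set(graph.nodes):
        sub.add_node(g)
    if sub.number_of_nodes() == 0:
        warnings.warn("no gene in enough pathways: empty subgraph")
    return sub


def classify_genes_vs_loci(
    genes: pd.DataFrame,
    loci: pd.DataFrame,
    near: tuple[int, int] = (35000, 10000),
    ld_window: tuple[int, int] = (500000, 500000),
) -> pd.DataFrame:
    """Label each gene against genome-wide significant loci.

    ``overlap`` when the strand-aware (upstream, downstream)-padded gene body
    intersects a locus; else ``ld_window`` when the symmetric LD-window
    padding intersects; else ``independent``.  Exactly one label per gene.
    """
    up, down = near
    ldu, ldd = ld_window
    labels = []
    for row in genes.itertuples(index=False):
        strand = getattr(row, "strand", "+")
        if strand == "+":
            near_lo, near_hi = row.start - up, row.end + down
        else:
            near_lo, near_hi = row.start - down, row.end + up
        ld_lo, ld_hi = row.start - ldu, row.end + ldd
        label = "independent"
        chrom_loci = loci[loci["chrom"] == row.chrom]
        for loc in chrom_loci.itertuples(index=False):
            if near_lo <= loc.end and loc.start <= near_hi:
                label = "overlap"
                break
        if label == "independent":
            for loc in chrom_loci.itertuples(index=False):
                if ld_lo <= loc.end and loc.start <= ld_hi:
                    label = "ld_window"
                    break
        labels.append(label)
    out = genes.copy()
    out["locus_class"] = labels
    return out


def metrics_table(metrics: list[NodeMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in metrics],
            "degree_norm": [m.degree_norm for m in metrics],
            "betweenness_norm": [m.betweenness_norm for m in metrics],
            "neglog10p": [m.neglog10p for m in metrics],
            "hub_degree": [m.hub_degree for m in metrics],
            "hub_betweenness": [m.hub_betweenness for m in metrics],
        }
    )
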