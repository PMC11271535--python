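"""Kinase-centric protein-interaction subnetworks with detection overlays.

Builds an undirected interaction graph from a BioGRID-style edge list,
restricts it to proteins detected in the experiment and to edges touching
at least one kinase, extracts the largest connected component, annotates
nodes with the number of cells in which each protein was detected, and
finds densely connected regions by greedy modularity maximization.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)


def read_edge_list(
    path: str | Path,
    source_col: str = "Official Symbol Interactor A",
    target_col: str = "Official Symbol Interactor B",
) -> nx.Graph:
    """Read an interaction edge list into an undirected graph.

    Duplicate edges (in either orientation) are merged and self-loops are
    dropped (a count is logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {source_col, target_col} - set(df.columns)
    if missing:
        raise SchemaError(f"edge list missing columns: {sorted(missing)}")
    graph = nx.Graph()
    n_self = 0
    for a, b in zip(df[source_col], df[target_col]):
        if a == b:
            n_self += 1
            continue
        graph.add_edge(a, b)
    logger.info(
        "read_edge_list: %d nodes, %d edges, %d self-loops dropped",
        graph.number_of_nodes(),
        graph.number_of_edges(),
        n_self,
    )
    return graph


def kinase_subnetwork(
    graph: nx.Graph, detected_genes, kinase_list
) -> nx.Graph:
    """Largest component of the detected, kinase-anchored subgraph.

    The input graph is induced on the detected genes, restricted to edges
    with at least one kinase endpoint, and the largest connected
    component is returned (ties broken by the lexicographically smallest
    member).  Nodes carry an ``is_kinase`` attribute.  An empty detected
    set yields an empty graph.
    """
    detected = set(detected_genes)
    kinases = set(kinase_list)
    induced = graph.subgraph(detected)
    sub = nx.Graph()
    sub.add_nodes_from(induced.nodes)
    sub.add_edges_from(
        (a, b) for a, b in induced.edges if a in kinases or b in kinases
    )
    components = [c for c in nx.connected_components(sub) if len(c) > 1]
    if not components:
        out = nx.Graph()
    else:
        largest = max(components, key=lambda c: (len(c), min(c)))
        # ties: prefer the component whose smallest member sorts first
        best_size = len(largest)
        tied = [c for c in components if len(c) == best_size]
        largest = min(tied, key=lambda c: min(c))
        out = nx.Graph(sub.subgraph(largest).copy())
    nx.set_node_attributes(
        out, {n: (n in kinases) for n in out.nodes}, "is_kinase"
    )
    return out


def overlay_detection(
    graph: nx.Graph, detection_counts: dict[str, int], n_cells: int
) -> nx.Graph:
    """Annotate nodes with per-protein cell-detection counts.

    Genes absent from ``detection_counts`` are annotated with 0.  The
    operation commutes with :func:`kinase_subnetwork`.
    """
    out = graph.copy()
    nx.set_node_attributes(
        out,
        {n: int(detection_counts.get(n, 0)) for n in out.nodes},
        "detection_count",
    )
    nx.set_node_attributes(out, n_cells, "n_cells")
    return out


def _internal_density(graph: nx.Graph, nodes: set) -> float:
    sub = graph.subgraph(nodes)
    n = len(nodes)
    if n < 2:
        return 0.0
    return 2.0 * sub.number_of_edges() / (n * (n - 1))


def dense_clusters(graph: nx.Graph, min_size: int = 4) -> list[set]:
    """Densely connected regions by greedy modularity maximization.

    Communities smaller than ``min_size`` are discarded; the rest are
    ordered by decreasing internal edge density (ties by the
    lexicographically smallest member), making the output deterministic.
    """
    if graph.number_of_edges() == 0:
        return []
    communities = nx.community.greedy_modularity_communities(graph)
    kept = [set(c) for c in communities if len(c) >= min_size]
    kept.sort(key=lambda c: (-_internal_density(graph, c), min(c)))
    return kept


def export_graph(
    graph: nx.Graph, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write a graph as GraphML plus node/edge TSVs.

    Returns the three written paths (``.graphml``, ``.nodes.tsv``,
    ``.edges.tsv``).
    """
    out_prefix = Path(out_prefix)
    graphml = out_prefix.with_suffix(".graphml")
    nx.write_graphml(graph, graphml)
    nodes = pd.DataFrame(
        [
            {"gene": n, **graph.nodes[n]}
            for n in sorted(graph.nodes)
        ]
    )
    edges = pd.DataFrame(
        sorted((min(a, b), max(a, b)) for a, b in graph.edges),
        columns=["source", "target"],
    )
    nodes_path = out_prefix.with_suffix(".nodes.tsv")
    edges_path = out_prefix.with_suffix(".edges.tsv")
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)
    return graphml, nodes_path, edges_path
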