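"""Gene activity networks (GANs) and their topology metrics.

A GAN is an undirected simple graph whose nodes are genes and whose edges
are strong positive expression correlations (edge weight = r, every weight
strictly above the construction threshold).  Unlike a directed regulatory
network, edges carry no direction — they record synchronized activity.
The module also assigns hierarchical gene clusters (average linkage on the
distance 1 - r), labelling singletons as "connectors".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "build_gan",
    "clustering_coefficient",
    "NetworkMetrics",
    "network_metrics",
    "metrics_percent_change",
    "GeneClusterAssignment",
    "hierarchical_gene_clusters",
]


def build_gan(
    table: pd.DataFrame,
    threshold: float = 0.99,
    gene_subset=None,
) -> nx.Graph:
    """Build a GAN from a correlation table: one edge per unordered pair
    with r strictly greater than ``threshold``.

    Nodes are the genes that appear in at least one passing pair; genes of
    ``gene_subset`` (or of the table) left without a single strong partner
    are reported in ``graph.graph['excluded']`` rather than added as
    isolated nodes.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    sub = table
    if gene_subset is not None:
        gene_subset = set(gene_subset)
        sub = table[table["gene_a"].isin(gene_subset) & table["gene_b"].isin(gene_subset)]
    passing = sub[sub["r"] > threshold]
    g = nx.Graph(threshold=threshold)
    condition = table.attrs.get("condition")
    if condition is not None:
        g.graph["condition"] = condition
    g.add_weighted_edges_from(
        zip(passing["gene_a"], passing["gene_b"], passing["r"].astype(float))
    )
    universe = (
        gene_subset
        if gene_subset is not None
        else set(sub["gene_a"]) | set(sub["gene_b"])
    )
    g.graph["excluded"] = sorted(universe - set(g.nodes))
    if len(table) == 0:
        warnings.warn("empty correlation table: GAN has no nodes")
    return g


def clustering_coefficient(graph: nx.Graph, node) -> float:
    """C_n = 2 e_n / (k_n (k_n - 1)) for an undirected network, where k_n is
    the number of neighbors of ``node`` and e_n the number of edges among
    them; defined as 0 when k_n < 2."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    neighbors = list(graph.neighbors(node))
    k = len(neighbors)
    if k < 2:
        return 0.0
    e = sum(
        1
        for i in range(k)
        for j in range(i + 1, k)
        if graph.has_edge(neighbors[i], neighbors[j])
    )
    return 2.0 * e / (k * (k - 1))


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    density: float
    avg_clustering: float
    node_clustering: dict = field(repr=False)
    n_components: int = 0
    component_sizes: list = field(default_factory=list)
    diameter: int | None = None                # largest component
    char_path_length: float | None = None      # largest component
    per_component: list = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_neighbors": self.avg_neighbors,
            "density": self.density,
            "avg_clustering": self.avg_clustering,
            "n_components": self.n_components,
            "component_sizes": self.component_sizes,
            "diameter": self.diameter,
            "char_path_length": self.char_path_length,
        }


def network_metrics(graph: nx.Graph) -> NetworkMetrics:
    """Node/edge counts, mean degree, density 2M/(N(N-1)), clustering
    coefficients, component census, and diameter / characteristic path
    length (reported for the largest component, with a per-component
    table)."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    m = graph.number_of_edges()
    degrees = [d for _, d in graph.degree()]
    node_cc = {v: clustering_coefficient(graph, v) for v in graph.nodes}
    components = sorted(nx.connected_components(graph), key=len, reverse=True)
    per_component = []
    for comp in components:
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            per_component.append({"size": 1, "diameter": 0, "char_path_length": 0.0})
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        dists = [
            lengths[u][v]
            for i, u in enumerate(comp)
            for j, v in enumerate(comp)
            if j > i
        ]
        per_component.append(
            {
                "size": len(comp),
                "diameter": int(max(dists)),
                "char_path_length": float(np.mean(dists)),
            }
        )
    largest = per_component[0]
    return NetworkMetrics(
        n_nodes=n,
        n_edges=m,
        avg_neighbors=float(np.mean(degrees)),
        density=(2.0 * m / (n * (n - 1))) if n > 1 else 0.0,
        avg_clustering=float(np.mean(list(node_cc.values()))),
        node_clustering=node_cc,
        n_components=len(components),
        component_sizes=[len(c) for c in components],
        diameter=largest["diameter"],
        char_path_length=largest["char_path_length"],
        per_component=per_component,
    )


def metrics_percent_change(metrics: NetworkMetrics, reference: NetworkMetrics) -> dict:
    """Generic percent change of scalar metrics relative to a reference
    network, 100 * (value - ref) / ref (NaN where the reference is 0 or
    undefined)."""
    out = {}
    a, b = metrics.as_dict(), reference.as_dict()
    for key in ("n_nodes", "n_edges", "avg_neighbors", "density",
                "avg_clustering", "diameter", "char_path_length"):
        x, ref = a.get(key), b.get(key)
        if x is None or ref in (None, 0):
            out[key] = float("nan")
        else:
            out[key] = 100.0 * (x - ref) / ref
    return out


@dataclass
class GeneClusterAssignment:
    labels: pd.Series          # per-gene label "I", "II", ... or "connector"
    n_clusters: int
    linkage_matrix: np.ndarray | None = field(default=None, repr=False)


def _roman(i: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for val, sym in numerals:
        while i >= val:
            out.append(sym)
            i -= val
    return "".join(out)


def hierarchical_gene_clusters(
    corr: pd.DataFrame,
    n_clusters: int | None = None,
    cut_height: float | None = None,
) -> GeneClusterAssignment:
    """Agglomerative clustering of GAN genes on the correlation distance
    d = 1 - r with average linkage.

    Clusters are labelled with roman numerals ordered by first appearance;
    singletons become "connector" genes.  Exactly one of ``n_clusters`` /
    ``cut_height`` selects the cut.
    """
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation submatrix must be square")
    genes = list(corr.index)
    if list(corr.columns) != genes:
        raise ValueError("correlation submatrix index/columns must match")
    if len(genes) == 1:
        return GeneClusterAssignment(
            labels=pd.Series(["connector"], index=genes, name="cluster"),
            n_clusters=0,
        )
    mat = corr.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("correlation submatrix must be symmetric")
    d = 1.0 - mat
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    if (n_clusters is None) == (cut_height is None):
        raise ValueError("specify exactly one of n_clusters or cut_height")
    if n_clusters is not None:
        flat = fcluster(z, t=n_clusters, criterion="maxclust")
    else:
        flat = fcluster(z, t=cut_height, criterion="distance")
    # relabel in order of first appearance; singletons -> connector
    sizes = pd.Series(flat).value_counts()
    labels = []
    mapping: dict = {}
    for lab in flat:
        if sizes[lab] == 1:
            labels.append("connector")
        else:
            if lab not in mapping:
                mapping[lab] = _roman(len(mapping) + 1)
            labels.append(mapping[lab])
    return GeneClusterAssignment(
        labels=pd.Series(labels, index=genes, name="cluster"),
        n_clusters=len(mapping),
        linkage_matrix=z,
    )
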