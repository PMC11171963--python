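"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive subset enumeration,
BFS by hand, closed-form formulas — and never calls the code paths it
checks.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque

import numpy as np


# --- graphs ----------------------------------------------------------------

def edge_set(graph):
    return {frozenset(e) for e in graph.edges() if len(set(e)) == 2}


def is_connected_subset(nodes, edges):
    """BFS connectivity of the induced subgraph on ``nodes``."""
    nodes = list(nodes)
    if not nodes:
        return False
    adj = {v: set() for v in nodes}
    nodeset = set(nodes)
    for e in edges:
        u, v = tuple(e)
        if u in nodeset and v in nodeset:
            adj[u].add(v)
            adj[v].add(u)
    seen = {nodes[0]}
    queue = deque([nodes[0]])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                queue.append(w)
    return len(seen) == len(nodes)


def brute_force_connected_subgraphs(graph, k):
    """Every connected induced k-subgraph by exhaustive C(N, k) search."""
    edges = edge_set(graph)
    return [
        subset
        for subset in itertools.combinations(sorted(graph.nodes), k)
        if is_connected_subset(subset, edges)
    ]


def naive_iso_class(nodes, edges):
    """Isomorphism-class key: lexicographically smallest edge list over all
    permutations (independent of the package's bitmask canonicalization)."""
    nodes = list(nodes)
    k = len(nodes)
    local = [
        frozenset((nodes.index(u), nodes.index(v)))
        for e in edges
        for u, v in [tuple(e)]
        if u in nodes and v in nodes
    ]
    best = None
    for perm in itertools.permutations(range(k)):
        mapped = tuple(sorted(tuple(sorted(perm[i] for i in pair)) for pair in local))
        if best is None or mapped < best:
            best = mapped
    return best


def brute_force_census(graph, k):
    """Counter iso-class-key -> count of connected induced k-subgraphs."""
    edges = edge_set(graph)
    counts: Counter = Counter()
    for subset in brute_force_connected_subgraphs(graph, k):
        counts[naive_iso_class(subset, edges)] += 1
    return counts


def bfs_shortest_paths(graph, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in graph.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def brute_force_metrics(graph):
    """Diameter / characteristic path length of the largest component,
    density, per-node clustering by neighbor intersection, component count."""
    nodes = list(graph.nodes)
    n = len(nodes)
    m = graph.number_of_edges()
    # components by repeated BFS
    remaining = set(nodes)
    components = []
    while remaining:
        start = next(iter(remaining))
        comp = set(bfs_shortest_paths(graph, start))
        components.append(comp)
        remaining -= comp
    components.sort(key=len, reverse=True)
    largest = components[0]
    dists = []
    for u in largest:
        du = bfs_shortest_paths(graph, u)
        dists.extend(du[v] for v in largest if v != u)
    clustering = {}
    for v in nodes:
        nbrs = set(graph.neighbors(v))
        k = len(nbrs)
        if k < 2:
            clustering[v] = 0.0
            continue
        e = sum(1 for a, b in itertools.combinations(sorted(nbrs), 2)
                if graph.has_edge(a, b))
        clustering[v] = 2.0 * e / (k * (k - 1))
    return {
        "n_nodes": n,
        "n_edges": m,
        "density": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        "avg_neighbors": float(np.mean([graph.degree(v) for v in nodes])),
        "clustering": clustering,
        "n_components": len(components),
        "component_sizes": [len(c) for c in components],
        "diameter": max(dists) if dists else 0,
        "char_path_length": float(np.mean(dists)) if dists else 0.0,
    }


def all_connected_graphs(k):
    """Every connected graph on k labeled vertices as an edge frozenset."""
    pairs = list(itertools.combinations(range(k), 2))
    out = []
    for bits in range(2 ** len(pairs)):
        edges = {frozenset(p) for i, p in enumerate(pairs) if bits >> i & 1}
        if is_connected_subset(range(k), edges):
            out.append(frozenset(edges))
    return out


# --- circuits --------------------------------------------------------------

def second_order_step(zeta, wn, t):
    """Textbook unit-step response of wn^2 / (s^2 + 2 zeta wn s + wn^2)."""
    t = np.asarray(t, dtype=float)
    if zeta < 1:
        wd = wn * np.sqrt(1 - zeta**2)
        return 1 - np.exp(-zeta * wn * t) * (
            np.cos(wd * t) + zeta / np.sqrt(1 - zeta**2) * np.sin(wd * t)
        )
    if zeta == 1:
        return 1 - np.exp(-wn * t) * (1 + wn * t)
    root = np.sqrt(zeta**2 - 1)
    s1, s2 = -wn * (zeta - root), -wn * (zeta + root)
    return 1 - (s2 * np.exp(s1 * t) - s1 * np.exp(s2 * t)) / (s2 - s1)


def second_order_overshoot(zeta):
    if zeta >= 1:
        return 0.0
    return float(np.exp(-np.pi * zeta / np.sqrt(1 - zeta**2)))
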