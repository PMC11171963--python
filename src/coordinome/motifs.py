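"""Recurring coordination modules (RCMs): connected-subgraph censuses.

An RCM is an isomorphism class of connected 3-6 node subgraphs that occurs
in a gene activity network more often than in random networks with the
same degree sequence.  Because GAN edges are symmetric correlations, RCMs
are undirected induced subgraphs, in contrast to the directed motifs of
gene regulatory networks.

The census enumerates every connected induced k-node subgraph exactly once
(ESU-style enumeration), pools isomorphic subgraphs through an exact
canonical labeling (minimum adjacency bit-string over all node
permutations, feasible for k <= 6), and assesses overrepresentation
against an ensemble of degree-preserving double-edge-swap randomizations.

Each motif class carries a complexity (edge count) and a normalized
entropy of its degree-share distribution,

    S = -sum_i q_i ln q_i / ln k,   q_i = d_i / sum_j d_j,

which is 1 exactly for regular motifs and below 1 otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MotifClass",
    "enumerate_connected_subgraphs",
    "canonical_label",
    "subgraph_census",
    "randomize_preserving_degrees",
    "MotifCensus",
    "motif_significance",
    "motif_entropy",
    "ComplexityBinning",
    "bin_and_compare",
    "default_complexity_bins",
]

_MIN_K, _MAX_K = 3, 6


# ---------------------------------------------------------------------------
# canonical labeling of <= 6-node graphs

@lru_cache(maxsize=8)
def _pair_positions(k: int):
    """Bit position of each unordered pair (i < j) in the adjacency mask."""
    pos = {}
    b = 0
    for i in range(k):
        for j in range(i + 1, k):
            pos[(i, j)] = b
            b += 1
    return pos


@lru_cache(maxsize=8)
def _permutation_maps(k: int):
    """For each permutation of k nodes, map new bit position -> old one."""
    pos = _pair_positions(k)
    maps = []
    for perm in itertools.permutations(range(k)):
        mapping = []
        for (i, j), new_bit in pos.items():
            a, b = perm[i], perm[j]
            if a > b:
                a, b = b, a
            mapping.append((new_bit, pos[(a, b)]))
        maps.append(tuple(mapping))
    return tuple(maps)


_canon_cache: dict = {}


def _canonical_mask(k: int, mask: int) -> int:
    """Minimum adjacency bit-string over all node permutations."""
    key = (k, mask)
    hit = _canon_cache.get(key)
    if hit is not None:
        return hit
    best = mask
    for mapping in _permutation_maps(k):
        m = 0
        for new_bit, old_bit in mapping:
            if mask >> old_bit & 1:
                m |= 1 << new_bit
        if m < best:
            best = m
    _canon_cache[key] = best
    return best


@dataclass(frozen=True)
class MotifClass:
    """A connected-subgraph isomorphism class on k nodes."""

    k: int
    canon: int    # canonical adjacency mask (upper triangle, row-major bits)

    @property
    def m(self) -> int:
        return bin(self.canon).count("1")

    @property
    def label(self) -> str:
        return f"{self.k}-{self.canon}"

    def as_graph(self) -> nx.Graph:
        g = nx.empty_graph(self.k)
        pos = _pair_positions(self.k)
        for (i, j), bit in pos.items():
            if self.canon >> bit & 1:
                g.add_edge(i, j)
        return g

    @property
    def degree_sequence(self) -> tuple:
        g = self.as_graph()
        return tuple(sorted((d for _, d in g.degree()), reverse=True))

    @property
    def entropy(self) -> float:
        return motif_entropy(self)


def canonical_label(subgraph: nx.Graph) -> MotifClass:
    """Canonical isomorphism-class identifier of a small graph.

    Isomorphic graphs map to the same :class:`MotifClass`; non-isomorphic
    graphs to distinct ones (exhaustive permutation search, k <= 6).
    """
    k = subgraph.number_of_nodes()
    if k > _MAX_K:
        raise ValueError(f"canonical labeling supports <= {_MAX_K} nodes, got {k}")
    nodes = list(subgraph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    pos = _pair_positions(k)
    mask = 0
    for u, v in subgraph.edges():
        i, j = index[u], index[v]
        if i > j:
            i, j = j, i
        mask |= 1 << pos[(i, j)]
    return MotifClass(k=k, canon=_canonical_mask(k, mask))


# ---------------------------------------------------------------------------
# ESU enumeration

def _adjacency(graph: nx.Graph):
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [set() for _ in nodes]
    bits = [0] * len(nodes)
    for u, v in graph.edges():
        if u == v:
            continue
        i, j = index[u], index[v]
        adj[i].add(j)
        adj[j].add(i)
        bits[i] |= 1 << j
        bits[j] |= 1 << i
    return nodes, adj, bits


def _esu(adj, k: int):
    """Yield every connected induced k-subgraph (as a tuple of int ids)
    exactly once."""
    n = len(adj)
    out = []

    def extend(sub, ext, nbhd, v):
        if len(sub) == k - 1:
            for w in ext:
                out.append(tuple(sub + [w]))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_nbhd = nbhd | adj[w] | {w}
            new_ext = ext | {u for u in adj[w] if u > v and u not in nbhd}
            extend(sub + [w], new_ext, new_nbhd, v)

    for v in range(n):
        ext = {u for u in adj[v] if u > v}
        if k == 1:
            out.append((v,))
        else:
            extend([v], ext, adj[v] | {v}, v)
    return out


def enumerate_connected_subgraphs(graph: nx.Graph, k: int) -> list:
    """All connected induced k-node subgraphs, each exactly once, as tuples
    of node labels."""
    if not _MIN_K <= k <= _MAX_K:
        raise ValueError(f"k must lie in [{_MIN_K}, {_MAX_K}]")
    if k > graph.number_of_nodes():
        warnings.warn("k exceeds node count: empty enumeration")
        return []
    nodes, adj, _ = _adjacency(graph)
    return [tuple(nodes[i] for i in sub) for sub in _esu(adj, k)]


def _census_counter(graph: nx.Graph, k: int) -> Counter:
    """Counter canonical-mask -> occurrences of connected k-subgraphs."""
    _, adj, bits = _adjacency(graph)
    pos = _pair_positions(k)
    counts: Counter = Counter()
    raw: Counter = Counter()
    for sub in _esu(adj, k):
        mask = 0
        for a in range(k):
            ba = bits[sub[a]]
            for b in range(a + 1, k):
                if ba >> sub[b] & 1:
                    mask |= 1 << pos[(a, b)]
        raw[mask] += 1
    for mask, c in raw.items():
        counts[_canonical_mask(k, mask)] += c
    return counts


def subgraph_census(graph: nx.Graph, k: int) -> dict:
    """Observed counts per motif class: {MotifClass: count}."""
    if not _MIN_K <= k <= _MAX_K:
        raise ValueError(f"k must lie in [{_MIN_K}, {_MAX_K}]")
    if k > graph.number_of_nodes():
        warnings.warn("k exceeds node count: empty census")
        return {}
    return {MotifClass(k, canon): c for canon, c in _census_counter(graph, k).items()}


# ---------------------------------------------------------------------------
# degree-preserving null model

def randomize_preserving_degrees(
    graph: nx.Graph,
    n_swaps: int | None = None,
    seed: int | None = None,
) -> nx.Graph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Swaps that would create self-loops or multi-edges are rejected, so the
    degree sequence is exactly preserved.  Defaults to 10 x |E| attempted
    swaps.  Graphs admitting no legal swap are returned as copies with a
    warning.
    """
    m = graph.number_of_edges()
    if m < 2:
        raise ValueError("degree-preserving randomization needs >= 2 edges")
    if n_swaps is None:
        n_swaps = 10 * m
    g = graph.copy()
    if n_swaps == 0:
        return g
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXError as exc:
        warnings.warn(f"edge swapping stopped early: {exc}")
    return g


# ---------------------------------------------------------------------------
# significance vs the null ensemble

@dataclass
class MotifCensus:
    """Observed motif counts with null-ensemble statistics.

    ``table`` columns: class_id, k, m, entropy, observed, null_mean,
    null_sd, z, p.  z is NaN (flagged) for classes with null_sd = 0;
    p is the empirical upper-tail probability (1 + #{null >= obs}) /
    (ensemble_size + 1).
    """

    k: int
    ensemble_size: int
    table: pd.DataFrame = field(repr=False)

    def observed(self) -> dict:
        return {
            MotifClass(self.k, int(row["canon"])): int(row["observed"])
            for _, row in self.table.iterrows()
        }

    @classmethod
    def from_observed(cls, k: int, counts: dict) -> "MotifCensus":
        """Census without a null ensemble (observed counts only)."""
        rows = [
            {
                "class_id": mc.label, "canon": mc.canon, "k": k, "m": mc.m,
                "entropy": motif_entropy(mc), "observed": c,
                "null_mean": float("nan"), "null_sd": float("nan"),
                "z": float("nan"), "p": float("nan"),
            }
            for mc, c in sorted(counts.items(), key=lambda kv: kv[0].canon)
        ]
        return cls(k=k, ensemble_size=0, table=pd.DataFrame(rows))


def motif_significance(
    graph: nx.Graph,
    k: int,
    ensemble_size: int = 1000,
    seed: int = 0,
    n_swaps: int | None = None,
) -> MotifCensus:
    """Motif census with overrepresentation statistics against
    ``ensemble_size`` degree-preserving randomizations."""
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if ensemble_size < 100:
        warnings.warn("ensemble_size < 100: empirical p-values are coarse")
    observed = _census_counter(graph, k)
    rng = np.random.default_rng(seed)
    null_counts: list = []
    classes = set(observed)
    for _ in range(ensemble_size):
        null = randomize_preserving_degrees(
            graph, n_swaps=n_swaps, seed=int(rng.integers(2**31))
        )
        c = _census_counter(null, k)
        null_counts.append(c)
        classes |= set(c)
    rows = []
    for canon in sorted(classes):
        obs = observed.get(canon, 0)
        nulls = np.array([c.get(canon, 0) for c in null_counts], dtype=float)
        mean, sd = float(nulls.mean()), float(nulls.std(ddof=0))
        z = (obs - mean) / sd if sd > 0 else float("nan")
        p = (1.0 + float((nulls >= obs).sum())) / (ensemble_size + 1.0)
        mc = MotifClass(k, canon)
        rows.append(
            {
                "class_id": mc.label, "canon": canon, "k": k, "m": mc.m,
                "entropy": motif_entropy(mc), "observed": obs,
                "null_mean": mean, "null_sd": sd, "z": z, "p": p,
            }
        )
    return MotifCensus(k=k, ensemble_size=ensemble_size, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# motif entropy and complexity binning

def motif_entropy(motif: MotifClass | nx.Graph) -> float:
    """Normalized Shannon entropy of a motif's degree-share distribution;
    1 exactly iff all degrees are equal."""
    if isinstance(motif, MotifClass):
        degrees = motif.degree_sequence
        k = motif.k
    else:
        degrees = [d for _, d in motif.degree()]
        k = motif.number_of_nodes()
    total = sum(degrees)
    if total == 0:
        raise ValueError("motif has no edges")
    if len(set(degrees)) == 1:
        return 1.0
    q = np.array(degrees, dtype=float) / total
    nz = q > 0
    return float(-(q[nz] * np.log(q[nz])).sum() / math.log(k))


def default_complexity_bins(k: int) -> dict:
    """Low/medium/high complexity ranges by edge count.

    For six-node motifs these are the printed ranges low 5-6, medium 7-12,
    high 13-15; for smaller k the edge range is too narrow for a meaningful
    three-way split, so each edge count forms its own bin.
    """
    if k == 6:
        return {"low": (5, 6), "medium": (7, 12), "high": (13, 15)}
    max_m = k * (k - 1) // 2
    return {f"m{m}": (m, m) for m in range(k - 1, max_m + 1)}


@dataclass
class ComplexityBinning:
    bins: dict                 # name -> (lo, hi) inclusive edge-count range
    frequency: dict            # name -> total observed occurrences
    log10_frequency: dict      # name -> log10(frequency + 1)
    s_avg: dict                # name -> occurrence-weighted mean motif entropy


def _bin_census(census: MotifCensus, bins: dict) -> ComplexityBinning:
    freq = {name: 0 for name in bins}
    s_num = {name: 0.0 for name in bins}
    for _, row in census.table.iterrows():
        for name, (lo, hi) in bins.items():
            if lo <= row["m"] <= hi:
                freq[name] += int(row["observed"])
                s_num[name] += row["entropy"] * int(row["observed"])
                break
    s_avg = {
        name: (s_num[name] / freq[name]) if freq[name] else float("nan")
        for name in bins
    }
    return ComplexityBinning(
        bins=dict(bins),
        frequency=freq,
        log10_frequency={n: math.log10(f + 1) for n, f in freq.items()},
        s_avg=s_avg,
    )


def bin_and_compare(
    census_a: MotifCensus,
    census_b: MotifCensus,
    bins: dict | None = None,
) -> dict:
    """Complexity binning of two censuses plus distribution comparison.

    Per census: per-bin total frequency (raw and log10(f+1)) and
    occurrence-weighted average motif entropy.  Normality of each census's
    class-frequency vector is checked with Shapiro-Wilk; the two vectors
    (aligned on the union of observed classes) are compared with the
    nonparametric Wilcoxon rank-sum test.
    """
    if census_a.k != census_b.k:
        raise ValueError("censuses must share the same motif size k")
    if len(census_a.table) == 0 or len(census_b.table) == 0:
        raise ValueError("empty census")
    bins = default_complexity_bins(census_a.k) if bins is None else bins
    canon_a = dict(zip(census_a.table["canon"], census_a.table["observed"]))
    canon_b = dict(zip(census_b.table["canon"], census_b.table["observed"]))
    union = sorted(set(canon_a) | set(canon_b))
    freq_a = np.array([canon_a.get(c, 0) for c in union], dtype=float)
    freq_b = np.array([canon_b.get(c, 0) for c in union], dtype=float)

    def _shapiro(x):
        if len(x) < 3 or np.ptp(x) == 0:
            return float("nan"), float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.shapiro(x)
        return float(res.statistic), float(res.pvalue)

    sw_a, sw_b = _shapiro(freq_a), _shapiro(freq_b)
    rs = stats.ranksums(freq_a, freq_b)
    return {
        "binning_a": _bin_census(census_a, bins),
        "binning_b": _bin_census(census_b, bins),
        "shapiro_a": {"stat": sw_a[0], "p": sw_a[1]},
        "shapiro_b": {"stat": sw_b[0], "p": sw_b[1]},
        "ranksum_stat": float(rs.statistic),
        "ranksum_p": float(rs.pvalue),
        "classes": union,
    }
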