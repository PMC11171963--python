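"""Synthetic replicate expression matrices and benchmark graphs.

The generator emulates a small developmental RNA-seq study: a handful of
conditions (a progenitor state, a committed state, nuclear-receptor
perturbations of each, and a disease/control pair), each measured in a few
biological replicates, with a subset of genes whose mean activity shifts
between conditions ("regulated" genes) and planted blocks of genes whose
replicate-to-replicate fluctuations are strongly coordinated within a
condition.

Coordination is planted through a shared latent replicate factor per
(block, condition).  A block gene's replicate deviation in condition ``c`` is

    s_g * ( sqrt(rho) * z + sqrt(1 - rho) * noise_sd * eps_g )

with ``z`` a unit-variance latent draw shared by the block and ``eps_g``
independent unit-variance noise.  The planted pair correlation is therefore

    s_i * s_j * rho / (rho + (1 - rho) * noise_sd**2),

which equals ``s_i * s_j * rho`` at ``noise_sd = 1`` and tends to ±1 as the
idiosyncratic noise vanishes.  Negative coordination is planted by per-gene
sign flips ``s_g`` within a block.  Genes outside every block fluctuate
independently with standard deviation ``noise_sd``.

Values are generated on a log2-like scale (Gaussian around condition means)
and exponentiated, so the emitted matrix holds positive "normalized
expression" values whose condition-mean ratios realize the planted log2
fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_expression",
    "generate_benchmark_graph",
    "default_study_spec",
]


@dataclass(frozen=True)
class BlockSpec:
    """A planted block of coordinated genes.

    Parameters
    ----------
    block_id
        Unique block label.
    genes
        Member gene ids (disjoint across blocks).
    rho
        Mapping condition -> target latent-factor share in [-1, 1].
        Conditions absent from the mapping are not planted (genes fluctuate
        independently there).  A negative value plants anticorrelation by
        assigning alternating signs to the members (unless ``signs`` is
        given explicitly).
    signs
        Optional per-gene signs (+1/-1) realizing negative coordination.
    """

    block_id: str
    genes: tuple
    rho: Mapping[str, float]
    signs: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"block {self.block_id!r} lists duplicate genes")
        for cond, r in self.rho.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(
                    f"block {self.block_id!r}: rho[{cond!r}]={r} outside [-1, 1]"
                )
        if self.signs is not None:
            object.__setattr__(self, "signs", tuple(int(s) for s in self.signs))
            if len(self.signs) != len(self.genes):
                raise ValueError("signs length must match genes length")
            if any(s not in (-1, 1) for s in self.signs):
                raise ValueError("signs must be +1 or -1")

    def effective_signs(self, condition: str) -> np.ndarray:
        """Per-gene signs used in ``condition`` (alternating for rho < 0)."""
        if self.signs is not None:
            return np.asarray(self.signs, dtype=float)
        if self.rho.get(condition, 0.0) < 0:
            return np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(self.genes))])
        return np.ones(len(self.genes))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic study.

    ``effect_profile`` maps a condition to the multiplier applied to each
    regulated gene's drawn log2 effect; by default only the second condition
    receives the full effect, so the (first, second) pair is the main
    developmental contrast.
    """

    n_genes: int
    conditions: tuple
    n_replicates: int = 3
    blocks: tuple = ()
    regulated_fraction: float = 0.0
    effect_size_log2: float = 1.0
    noise_sd: float = 0.2
    effect_profile: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ValueError("conditions must be nonempty and unique")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.regulated_fraction <= 1.0:
            raise ValueError("regulated_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        seen: set = set()
        gene_set = set(self.gene_ids())
        for blk in self.blocks:
            members = set(blk.genes)
            if members & seen:
                raise ValueError(f"block {blk.block_id!r} overlaps another block")
            if not members <= gene_set:
                raise ValueError(f"block {blk.block_id!r} references unknown genes")
            for cond in blk.rho:
                if cond not in self.conditions:
                    raise ValueError(
                        f"block {blk.block_id!r} references unknown condition {cond!r}"
                    )
            seen |= members
        if self.effect_profile is not None:
            unknown = set(self.effect_profile) - set(self.conditions)
            if unknown:
                raise ValueError(f"effect_profile references unknown conditions {unknown}")

    def gene_ids(self) -> list:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def resolved_effect_profile(self) -> dict:
        if self.effect_profile is not None:
            return dict(self.effect_profile)
        if len(self.conditions) >= 2:
            return {self.conditions[1]: 1.0}
        return {}


@dataclass
class GroundTruth:
    """Planted structure of a generated matrix (one entry per gene)."""

    genes: list
    block_of: dict            # gene -> block_id or None
    sign_of: dict             # gene -> {condition: +/-1} (block genes only)
    regulated: dict           # gene -> bool
    effect_log2: dict         # gene -> signed log2 effect (0 for non-regulated)
    block_rho: dict           # (block_id, condition) -> rho
    noise_sd: float

    def expected_correlation(self, gene_a: str, gene_b: str, condition: str) -> float:
        """Planted Pearson correlation between two genes in a condition."""
        ba, bb = self.block_of.get(gene_a), self.block_of.get(gene_b)
        if ba is None or ba != bb or gene_a == gene_b:
            return 0.0
        rho = abs(self.block_rho.get((ba, condition), 0.0))
        if rho == 0.0:
            return 0.0
        shared = rho / (rho + (1.0 - rho) * self.noise_sd**2)
        sa = self.sign_of[gene_a][condition]
        sb = self.sign_of[gene_b][condition]
        return sa * sb * shared

    def block_members(self, block_id: str) -> list:
        return [g for g in self.genes if self.block_of.get(g) == block_id]


def generate_expression(spec: SyntheticSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a genes x samples expression matrix with planted structure.

    Returns the matrix (columns ``<condition>_<replicate>``, positive
    values) and the :class:`GroundTruth` describing what was planted.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    n = spec.n_genes
    idx = {g: i for i, g in enumerate(genes)}

    baseline = rng.uniform(4.0, 10.0, n)  # log2-scale baseline abundance

    n_reg = int(round(spec.regulated_fraction * n))
    reg_idx = rng.choice(n, size=n_reg, replace=False) if n_reg else np.array([], dtype=int)
    effect = np.zeros(n)
    if n_reg:
        # tight spread around the mean effect so regulated genes separate
        # cleanly from the unregulated background
        magnitude = np.abs(rng.normal(spec.effect_size_log2,
                                      spec.effect_size_log2 / 4.0, n_reg))
        sign = rng.choice([-1.0, 1.0], n_reg)
        effect[reg_idx] = sign * magnitude
    profile = spec.resolved_effect_profile()

    block_of: dict = {g: None for g in genes}
    sign_of: dict = {}
    block_rho: dict = {}
    for blk in spec.blocks:
        for g in blk.genes:
            block_of[g] = blk.block_id
        for cond, r in blk.rho.items():
            block_rho[(blk.block_id, cond)] = r
        for g in blk.genes:
            sign_of[g] = {}
        for cond in spec.conditions:
            s = blk.effective_signs(cond)
            for g, sg in zip(blk.genes, s):
                sign_of[g][cond] = float(sg)

    columns = []
    data = []
    for cond in spec.conditions:
        mult = profile.get(cond, 0.0)
        mean = baseline + mult * effect
        eps = rng.standard_normal((n, spec.n_replicates))
        dev = spec.noise_sd * eps
        for blk in spec.blocks:
            rho = abs(blk.rho.get(cond, 0.0))
            if rho == 0.0:
                continue
            z = rng.standard_normal(spec.n_replicates)
            signs = blk.effective_signs(cond)
            rows = [idx[g] for g in blk.genes]
            shared = math.sqrt(rho) * z
            own = math.sqrt(1.0 - rho) * spec.noise_sd * eps[rows]
            dev[rows] = signs[:, None] * (shared[None, :] + own)
        log2_vals = mean[:, None] + dev
        for r in range(spec.n_replicates):
            columns.append(f"{cond}_{r + 1}")
            data.append(log2_vals[:, r])
    matrix = pd.DataFrame(
        np.power(2.0, np.column_stack(data)), index=pd.Index(genes, name="gene"),
        columns=columns,
    )

    truth = GroundTruth(
        genes=genes,
        block_of=block_of,
        sign_of=sign_of,
        regulated={g: i in set(reg_idx.tolist()) for i, g in enumerate(genes)},
        effect_log2={g: float(effect[i]) for i, g in enumerate(genes)},
        block_rho=block_rho,
        noise_sd=spec.noise_sd,
    )
    return matrix, truth


STUDY_CONDITIONS = ("NPC", "NPC_TK-", "NCC", "NCC_TK-", "NCC_NLS", "CTRL", "SCZ")


def default_study_spec(n_genes: int = 600, seed: int = 0) -> SyntheticSpec:
    """Spec emulating the study design at desk scale.

    Five developmental/perturbation conditions plus a control/disease pair,
    three biological replicates each.  About 29% of genes are regulated
    across the progenitor -> committed transition (the study's 4646 of
    16,137), with a mean effect of one log2 unit.  Planted blocks realize
    the deconstruction/reconstruction pattern: the progenitor-state block
    dissolves in the committed state and vice versa, perturbed conditions
    retain only weakened coordination, and the disease condition gains a
    block absent from its control.
    """
    width = max(4, len(str(n_genes - 1)))
    gid = lambda i: f"g{i:0{width}d}"
    b = 25  # genes per block
    if n_genes < 5 * b:
        raise ValueError("default study spec needs at least 125 genes")
    blocks = (
        BlockSpec("npc_block", tuple(gid(i) for i in range(0, b)),
                  {"NPC": 0.99, "NPC_TK-": 0.5}),
        BlockSpec("ncc_block", tuple(gid(i) for i in range(b, 2 * b)),
                  {"NCC": 0.99, "NCC_TK-": 0.4, "NCC_NLS": 0.6}),
        BlockSpec("ncc_block2", tuple(gid(i) for i in range(2 * b, 3 * b)),
                  {"NCC": 0.99, "NCC_TK-": 0.5}),
        BlockSpec("neg_block", tuple(gid(i) for i in range(3 * b, 4 * b)),
                  {"NCC": -0.95}),
        BlockSpec("scz_block", tuple(gid(i) for i in range(4 * b, 5 * b)),
                  {"SCZ": 0.99, "CTRL": 0.3}),
    )
    return SyntheticSpec(
        n_genes=n_genes,
        conditions=STUDY_CONDITIONS,
        n_replicates=3,
        blocks=blocks,
        regulated_fraction=0.29,
        effect_size_log2=1.0,
        noise_sd=0.2,
        effect_profile={"NCC": 1.0, "NCC_TK-": 0.7, "NCC_NLS": 1.2, "SCZ": 0.8},
        seed=seed,
    )


def generate_benchmark_graph(kind: str, params: Mapping | None = None,
                             seed: int | None = None) -> nx.Graph:
    """Benchmark graphs with known structure for network/motif tests.

    Kinds: ``path`` (n), ``complete`` (n), ``star`` (n leaves),
    ``erdos_renyi`` (n, p), ``planted_motif`` (motif_size, n_motifs,
    n_background, p, clique=True) which embeds disjoint copies of a k-clique
    (or k-cycle with ``clique=False``) in a sparse random background, each
    copy tethered to the background by one bridge edge.
    """
    params = dict(params or {})
    if kind == "path":
        return nx.path_graph(int(params["n"]))
    if kind == "complete":
        return nx.complete_graph(int(params["n"]))
    if kind == "star":
        return nx.star_graph(int(params["n"]))
    if kind == "erdos_renyi":
        return nx.gnp_random_graph(int(params["n"]), float(params["p"]), seed=seed)
    if kind == "planted_motif":
        k = int(params.get("motif_size", 4))
        if not 3 <= k <= 6:
            raise ValueError("motif_size must be in [3, 6]")
        n_motifs = int(params.get("n_motifs", 10))
        n_bg = int(params.get("n_background", 50))
        p = float(params.get("p", 0.05))
        clique = bool(params.get("clique", True))
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(n_bg, p, seed=int(rng.integers(2**31)))
        next_node = n_bg
        for _ in range(n_motifs):
            nodes = list(range(next_node, next_node + k))
            next_node += k
            motif = nx.complete_graph(k) if clique else nx.cycle_graph(k)
            g.add_edges_from((nodes[u], nodes[v]) for u, v in motif.edges())
            anchor = int(rng.integers(n_bg))
            g.add_edge(nodes[int(rng.integers(k))], anchor)
        return g
    raise ValueError(f"unknown benchmark graph kind {kind!r}")
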