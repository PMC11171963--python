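# coordinome

Genome-wide **gene-activity coordination** analysis for replicate expression
data: from a genes × samples matrix to correlation statistics, gene activity
networks, recurring coordination modules, and an electrical-circuit model of
how those modules transmit information.

## The problem

When neural progenitor cells commit to a neuronal fate, thousands of genes
change activity — but far more genes change *together*. Beyond per-gene fold
changes, the replicate-to-replicate fluctuations of gene pairs are
coordinated, and the pattern of that coordination is itself developmentally
regulated: strongly correlated gene sets present in the progenitor state
dissolve after the transition and are replaced by different ones, a
deconstruction/reconstruction of the coordinated genome. `coordinome`
implements this analysis as a tested, reusable pipeline for anyone with
condition × replicate expression matrices (≥ 2, typically 3 biological
replicates per condition), together with a synthetic-data generator that
plants known coordination structure so every stage has a ground-truth test
surface.

## The method

For each condition, per-gene replicate vectors are z-scored
(mean 0, sd 1) and coordination of a gene pair is the Pearson correlation
*r* ∈ [−1, +1] across replicates. On top of this the package provides:

- **Fold-change statistics** — log₂ of condition-mean ratios (a 2-fold
  change is +1), gene-group set algebra, *t*/Kolmogorov–Smirnov/χ²
  comparisons of fold-change distributions, and *k*-means clustering with
  the cluster number chosen by the Calinski–Harabasz criterion.
- **Coordination statistics** — all-pairs correlation tables within or
  between gene sets, frequency histograms over [−1, 1] with χ² comparisons,
  and the normalized Shannon entropy
  S = −Σ pᵢ ln pᵢ / ln K of a binned correlation distribution (S = 1
  uniform, S = 0 a point mass; lower S = more ordered coordination).
- **Strong-pair calibration** — each side of the correlation distribution is
  fitted to a Beta(α, β) law by maximum likelihood; the 95% quantile defines
  the strong-correlation thresholds r⁺ and r⁻. Strong pairs are counted and
  summarized by their average correlation r_avg, and pairs selected in a
  reference condition can be re-measured in any other.
- **Gene activity networks (GANs)** — undirected graphs with an edge for
  every pair with r above a threshold (0.99 by default), with node/edge
  counts, average neighbors, diameter, characteristic path length,
  clustering coefficient Cₙ = 2eₙ/(kₙ(kₙ−1)), density 2M/(N(N−1)),
  connected components, and hierarchical gene clusters (average linkage on
  d = 1 − r, singletons labelled connectors).
- **Recurring coordination modules (RCMs)** — exact enumeration of all
  connected induced 3–6-node subgraphs (ESU), pooled by exact canonical
  labeling, with overrepresentation z-scores and empirical p-values against
  degree-preserving double-edge-swap null ensembles, complexity binning by
  edge count, and a per-motif entropy of the degree-share distribution.
- **R-L-C circuit model** — a motif with m edges is a series
  resistor–inductor–capacitor stage with effective inductance
  L_eff = L_unit/m, natural frequency ωₙ = 1/√(L_eff C) and damping ratio
  ζ = (R/2)√(C/L_eff). Calibrating R so a chosen edge count (default 10) is
  critically damped gives ζ(m) = √(m/10): sparse modules ring (sub-critical,
  oscillatory overshoot), dense ones over-damp and attenuate the transient.
  Cascaded transfer functions H = H₁H₂… model transmission between modules.

## Worked example

```python
from coordinome import (default_study_spec, generate_expression,
    zscore_standardize, pairwise_pearson, fit_beta_thresholds, strong_pairs,
    histogram_correlations, coordination_entropy, build_gan, network_metrics,
    transmission_analysis)

spec = default_study_spec(n_genes=300, seed=0)   # 7 conditions x 3 replicates
matrix, truth = generate_expression(spec)

for cond in ("NPC", "NCC"):
    z = zscore_standardize(matrix, cond)
    table = pairwise_pearson(z)
    thr = fit_beta_thresholds(table)
    summary = strong_pairs(table, thr)
    S = coordination_entropy(histogram_correlations(table))
    gan = build_gan(table, 0.99, gene_subset=truth.block_members("npc_block"))
    print(f"{cond}: r+ = {thr.r_pos:.4f}, strong pairs = {summary.n_positive}, "
          f"S = {S:.3f}, progenitor-block GAN: "
          f"{gan.number_of_nodes()} nodes / {gan.number_of_edges()} edges")
```

prints

```
NPC: r+ = 0.9975, strong pairs = 1261, S = 0.950, progenitor-block GAN: 25 nodes / 300 edges
NCC: r+ = 0.9981, strong pairs = 1205, S = 0.936, progenitor-block GAN: 21 nodes / 13 edges
```

The block of 25 genes planted with ρ = 0.99 in the progenitor state forms a
complete 300-edge GAN there and collapses to 13 residual edges after the
transition — the deconstruction/reconstruction pattern the pipeline is built
to detect. Feeding module complexities into the circuit model:

```python
for m_edges in (6, 10, 14):
    res = transmission_analysis(m_edges, levels=2)
    print(f"m = {m_edges:2d}: zeta = {res['zeta']:.3f}, {res['regime']:13s} "
          f"overshoot = {res['terminal_overshoot']:.4f}")
```

```
m =  6: zeta = 0.775, sub-critical  overshoot = 0.0281
m = 10: zeta = 1.000, critical      overshoot = 0.0000
m = 14: zeta = 1.183, over-critical overshoot = 0.0000
```

A six-edge module passes the step stimulus on with ringing (noise), the
ten-edge module transmits it cleanly, and the fourteen-edge module damps the
transient — connectivity tunes the trade-off between noise suppression and
signal transmission.

The same stages are available from the shell:

```bash
coordinome simulate --out sim/ --seed 3 --n-genes 300
coordinome correlate --matrix sim/expression.tsv --condition NCC --out corr/
coordinome gan --correlations corr/correlations.tsv.gz --threshold 0.99 --out gan/
coordinome motifs --graph gan/gan.sif --k 3..4 --ensemble 1000 --out motifs/
coordinome circuit --census motifs/census_k4.tsv --levels 2 --out circuit/
```

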