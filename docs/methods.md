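# Methods

This note documents the models implemented by `coordinome`, the design of
the synthetic-data generator, the parameter defaults, and the numerical
choices made where the design was genuinely open.

## 1. Coordination model

Expression is assumed to be already-normalized (the pipeline does not model
library size, GC content, or count noise). For a condition with n ≥ 2
replicates, each gene's replicate vector is standardized to mean 0 and
sample sd 1 (ddof = 1); zero-variance genes cannot be standardized and are
excluded with a warning rather than propagated as NaN. Coordination of a
gene pair is the Pearson correlation of the standardized vectors, computed
per condition over that condition's replicates only — conditions are never
pooled, so "coordination in state A" and "in state B" are independent
measurements on the same genes. Pearson r is invariant under the
standardization (asserted to 1e−10 in the tests).

With n = 3 replicates a sample correlation carries only one effective
degree of freedom, and the null density of r is arcsine-like,
f(r) ∝ (1 − r²)^(−1/2): null pairs pile up near ±1, which is why "strong"
thresholds from real replicate designs sit deep in the tails (≈ 0.95–0.997)
and why strong-pair counts must always be compared against a calibrated
threshold, never an intuition about |r| being "large".

### Correlation histograms, χ², entropy

Correlation tables are binned on [−1, 1]; the default is 50 equal bins
(width 0.04), which resolves the ±0.96 tail region. Two histograms are
compared with a χ² statistic in which the second table's bin proportions,
scaled to the first's total, serve as expected counts; adjacent bins are
pooled until every expected count reaches 5. The entropy of a histogram is
the normalized Shannon entropy S = −Σ pᵢ ln pᵢ / ln K over all K bins
(0 ln 0 ≡ 0), giving S ∈ [0, 1] with S = 1 for a uniform histogram. The
natural-log/ln K normalization is a documented choice: it is the convention
that produces entropies on a [0, 1] scale comparable across bin counts.

### Beta-model thresholds

The positive side of a correlation distribution, {r : r > 0}, is fitted to
a Beta(α, β) law by maximum likelihood with the support fixed to (0, 1)
(the negative side fits {|r| : r < 0}). The threshold is the fitted
distribution's 95% quantile (level configurable), negated on the negative
side. Values are clipped to [1e−9, 1 − 1e−9] before fitting so perfectly
correlated pairs keep a finite log-likelihood; the clip is far below the
quantile resolution of any realistic sample. A sample with fewer than 50
values on the requested side, or with zero spread, is rejected. The
published fixed cutoffs — 0.99 for network edges, ±0.96 for strong pairs —
are available as `ThresholdPair.fixed(...)` when the fit is not wanted.

## 2. Synthetic data

The generator emulates a small developmental study: seven conditions
(progenitor NPC, committed NCC, dominant-negative perturbations NPC^TK−^ and
NCC^TK−^, an overexpression condition NCC^NLS^, and a control/disease pair
CTRL/SCZ), three biological replicates each, and a regulated fraction of
0.29 — the share of the expressed genome whose mean activity shifts across
the main transition in studies of this design (≈ 4.6k of 16k genes).
Defaults: mean effect 1.0 log₂ unit, replicate noise sd 0.2 on the log₂
scale. Values are drawn as Gaussians around condition means on a log₂-like
scale and exponentiated, so the emitted matrix is positive and
condition-mean ratios realize the planted fold changes.

Regulated genes receive a signed effect whose magnitude is |N(effect,
effect/4)|: concentrated around the mean effect so that regulated genes
separate cleanly from the unregulated background (the realized mean |log₂
fold change| matches the spec'd effect, and essentially all regulated genes
exceed half of it). A per-condition `effect_profile` scales each gene's
effect per condition, which is how the perturbed conditions (TK−, NLS,
SCZ) receive attenuated or amplified versions of the transition effect.

### Planted coordination

Coordination is planted through one latent factor per (block, condition).
A block gene's replicate deviation in condition c is

    s_g · ( √ρ · z  +  √(1−ρ) · σ · ε_g ),      z, ε_g ~ N(0, 1),

with σ = `noise_sd`, z shared across the block, and s_g a per-gene sign
(negative coordination is planted by alternating signs, triggered
automatically by a negative ρ). The planted pair correlation is therefore

    r_planted = s_i s_j · ρ / (ρ + (1−ρ) σ²),

which equals s_i s_j ρ at σ = 1 and tends to ±1 as the idiosyncratic noise
vanishes. This parameterization was chosen deliberately: the latent
fluctuation is the biological signal (a coordinated activity program), and
`noise_sd` is the replicate-level technical noise around it. At the default
σ = 0.2 a block planted at ρ = 0.99 has r_planted ≈ 0.9996, so its pairs
survive even the deep-tail thresholds that three-replicate designs
produce — matching the empirical situation the pipeline targets, where
strongly coordinated pairs are detected above ≈ 0.96–0.997 despite n = 3.
Planted ρ refers to the log-activity scale; at the default noise level the
distortion from exponentiation is < 1%, and convergence of empirical
within-block correlation to ρ is verified at σ = 1 with 12 replicates,
where the small-n bias of the sample correlation (≈ ρ(1−ρ²)/(2(n−1))) is
inside the 0.05 test tolerance.

What the generator does **not** emulate: read-level count noise,
library-size and GC biases, dropout, gene-length effects, and realistic
correlation structure among "background" genes (non-block genes are
mutually independent). Passing tests therefore demonstrate that the
pipeline's inferences are correct when its model assumptions hold, not that
those assumptions hold in any particular RNA-seq data set.

Benchmark graphs (`generate_benchmark_graph`) provide known topologies for
the network stages: paths, cliques, stars, Erdős–Rényi graphs, and a
planted-motif graph embedding a stated number of k-cliques (or k-cycles) in
a sparse background (default 60-node background at p = 0.04), each copy
tethered by one bridge edge so planted and background structure mix.

## 3. Fold-change statistics

Fold changes are log₂ of condition-mean ratios (base 2 is fixed by the
convention that a 2-fold change is 1). Genes with a non-positive mean in
either condition are flagged and excluded. The t comparison of two
fold-change vectors is paired when both vectors are aligned over the same
genes, two-sample otherwise (both exposed; paired is the default for
identical gene sets). K-S runs on unbinned values; χ² on a shared binning
with the same pooling rule as for correlation histograms. k-means uses 10
restarts with a fixed seed and squared-Euclidean distance; the cluster
number maximizes the Calinski–Harabasz score over the scanned range, ties
broken toward smaller k (parsimony). A degenerate input (all points
identical) is rejected rather than clustered.

## 4. GANs

A GAN keeps every pair with r **strictly** greater than the threshold
(default 0.99, positive side only — negative-pair networks are out of
scope). Genes left without a strong partner are reported as excluded rather
than added as isolated nodes, so "average number of neighbors" is computed
over network members only. Diameter and characteristic path length are
undefined for fragmented graphs and are therefore reported for the largest
connected component, with a per-component table alongside. Hierarchical
clusters use average linkage on d = 1 − r; the cut is by cluster count or
height (caller's choice), singleton clusters are relabelled "connector",
and cluster labels are roman numerals in order of first appearance, so the
labelling is stable under gene-order permutation (up to label names).
A generic percent-change report compares two metric sets; it makes no claim
to reproduce any particular published normalization.

## 5. Motif census

RCMs are **undirected induced** connected subgraphs of 3–6 nodes.
Enumeration is ESU: each connected induced k-subgraph is emitted exactly
once, verified against exhaustive C(N, k) subset enumeration on random
graphs. Isomorphic subgraphs are pooled by an exact canonical form — the
minimum adjacency bit-string over all k! node permutations, memoized per
adjacency pattern; at k ≤ 6 this is at most 720 permutations over 15 bits
and provably correct. The null model holds the degree sequence fixed via
double-edge swaps (default 10·|E| attempted swaps, rejections on
self-loops/multi-edges), the standard reading of "random networks with the
same connectivity properties". Significance per class: z = (obs − null
mean)/null sd (NaN-flagged when the null sd is 0) and the empirical
upper-tail p = (1 + #{null ≥ obs})/(ensemble + 1); ensembles below 100 are
warned about.

Complexity is the motif's edge count. For six-node motifs the default bins
are low 5–6, medium 7–12, high 13–15 edges; for smaller k the edge range is
too narrow for a meaningful three-way split and each edge count forms its
own bin. A motif's entropy is the normalized Shannon entropy of its
degree-share distribution, S = −Σ qᵢ ln qᵢ / ln k with qᵢ = dᵢ/Σdⱼ — 1
exactly iff the motif is regular. This topology-only definition yields
values on the same [0, 1] scale as published module entropies (triangles
1.0, 3-paths 0.946, 3-stars 0.896) but is a stand-in for any particular
published formula and is not claimed to reproduce specific printed
averages. Bin-level S_avg weights each class by its occurrence count.
Census frequency vectors are compared with the Wilcoxon rank-sum test after
a Shapiro–Wilk normality check (frequency curves of real censuses are
heavy-tailed, hence the nonparametric default).

## 6. R-L-C circuit model

Each module is a lumped series R-L-C stage driven by a source, output
across C. The mapping from topology is deliberately minimal: every edge
contributes one unit inductor in parallel, L_eff = L_unit/m, while R and C
stay constant — the only simple monotone mapping consistent with denser
modules damping harder. How a multi-gene module's R and C would aggregate
is not identifiable from topology, so they are held constant; the lumped
abstraction is a stand-in, not a per-node circuit solution. All quantities
are dimensionless with L_unit = C = 1 by default.

The stage transfer function is H(s) = ωₙ²/(s² + 2ζωₙs + ωₙ²) with unit DC
gain; cascades multiply numerators and denominators. Step responses are
computed by simulating the state-space realization on a uniform grid; the
input is piecewise constant, so the zero-order-hold discretization is exact
at the grid points, and single stages match the textbook closed forms at
machine precision (tested to a 1e−4 sup-norm bound). Overshoot is the peak
excess over the DC gain (clipped at 0), settling time the last exit from
the ±2% band, and a response is flagged oscillatory when it crosses its
final value more than once. Calibration chooses R so a reference edge count
m_crit (default 10) is critically damped, giving ζ(m) = √(m/m_crit),
strictly increasing in m. Because every stage has unit DC gain, no cascade
loses steady-state signal; "signal loss" in over-critical modules is
operationalized as transient attenuation, reported as the terminal
response's peak slew rate relative to the critical case. Near the critical
point (e.g. m = 9, ζ ≈ 0.95) a cascade's theoretical overshoot is positive
but below ~1e−5 and numerically indistinguishable from 0; tests assert
strictly positive overshoot only safely below critical (m ≤ 8) and exact
zero at or above it.

## 7. Problem sizes and determinism

All simulations are sized for a desk-scale run: 300–500 genes for
end-to-end coordination analyses (124,750 pairs at 500 genes), 1000-graph
null ensembles for the planted-clique benchmark, 100 random graphs of ≤ 15
nodes for the enumeration cross-check. These sizes were chosen so the full
pipeline reruns in well under a minute while keeping every statistical
margin wide (sensitivity, ARI and edge-fraction margins hold across seeds).
Every stochastic step takes an explicit seed; fixed seeds give bit-identical
matrices, edge sets, and null ensembles.

## 8. Known limitations

- Pearson-only coordination: no partial correlations, mutual information,
  or lagged structure; three-replicate correlations are inherently noisy
  and the pipeline's guarantees are about calibrated thresholds, not about
  individual pair estimates.
- The motif census is exhaustive and intended for GAN-scale graphs
  (hundreds of nodes, sparse); it is not a sampling estimator for large
  dense networks, and motif sizes above 6 are unsupported.
- The circuit model is a qualitative, lumped abstraction linking module
  complexity to damping class; its parameters are not fit to data.
- Upstream differential-expression calling is out of scope: regulated /
  dysregulated gene sets are inputs (files or synthetic ground truth).
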