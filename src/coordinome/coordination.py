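"""Pairwise gene-activity coordination within a condition.

Replicate values are z-scored per gene (mean 0, sd 1 across the condition's
replicates) and coordination between two genes is their Pearson correlation
across replicates: r > 0 means both genes move together, r < 0 means they
move in opposite directions.  The module builds per-condition correlation
tables, frequency histograms with chi-square comparisons, a beta-model
calibration of "strong" correlation thresholds, strong-pair summaries with
side-wise average correlations (r_avg), and the normalized Shannon entropy
of a correlation histogram (lower entropy = more ordered coordination).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import _chi2_from_counts, condition_columns

__all__ = [
    "zscore_standardize",
    "pairwise_pearson",
    "CorrelationHistogram",
    "histogram_correlations",
    "histogram_and_chi2",
    "coordination_entropy",
    "BetaFit",
    "ThresholdPair",
    "fit_beta_threshold",
    "fit_beta_thresholds",
    "StrongPairSummary",
    "strong_pairs",
    "reevaluate_pairs",
    "default_bin_edges",
]

#: 50 equal bins on [-1, 1] (width 0.04) resolve the +/-0.96 tails.
DEFAULT_N_BINS = 50


def default_bin_edges(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    return np.linspace(-1.0, 1.0, n_bins + 1)


def zscore_standardize(matrix: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-gene z-scores across one condition's replicates.

    Zero-variance genes cannot be standardized; they are dropped with a
    warning and listed in ``result.attrs['excluded']``.
    """
    cols = condition_columns(matrix, condition)
    if len(cols) < 2:
        raise ValueError(f"condition {condition!r} needs >= 2 replicates")
    sub = matrix[cols].astype(float)
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance genes excluded from z-scoring "
            f"in condition {condition!r}"
        )
    sub = sub.loc[~flat]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[~flat], axis=0)
    z.attrs["condition"] = condition
    z.attrs["excluded"] = matrix.index[flat].tolist()
    return z


def _canonical_pairs(gene_a, gene_b):
    """Order each pair lexicographically so unordered pairs are unique."""
    gene_a = np.asarray(gene_a, dtype=object)
    gene_b = np.asarray(gene_b, dtype=object)
    swap = gene_a > gene_b
    lo = np.where(swap, gene_b, gene_a)
    hi = np.where(swap, gene_a, gene_b)
    return lo, hi


def pairwise_pearson(
    z: pd.DataFrame,
    set_x=None,
    set_y=None,
    condition: str | None = None,
) -> pd.DataFrame:
    """All-pairs Pearson correlations of z-scored replicate vectors.

    Within-set mode (``set_y`` omitted or equal to ``set_x``) yields every
    unordered pair once.  Cross-set mode yields every x-y pair, excluding
    identical-gene pairs and storing each unordered pair once even when the
    sets overlap.  Returns a table with columns ``gene_a, gene_b, r``.
    """
    if z.shape[1] < 2:
        raise ValueError("need >= 2 replicates to correlate")
    genes = z.index
    x = sorted(genes if set_x is None else (set(set_x) & set(genes)))
    y = None if set_y is None else sorted(set(set_y) & set(genes))
    condition = condition or z.attrs.get("condition")

    n = z.shape[1]
    if y is None or set(y) == set(x):
        zx = z.loc[x].to_numpy()
        corr = (zx @ zx.T) / (n - 1)
        iu, ju = np.triu_indices(len(x), k=1)
        ga = np.asarray(x, dtype=object)[iu]
        gb = np.asarray(x, dtype=object)[ju]
        r = corr[iu, ju]
    else:
        zx = z.loc[x].to_numpy()
        zy = z.loc[y].to_numpy()
        corr = (zx @ zy.T) / (n - 1)
        ii, jj = np.meshgrid(np.arange(len(x)), np.arange(len(y)), indexing="ij")
        ga = np.asarray(x, dtype=object)[ii.ravel()]
        gb = np.asarray(y, dtype=object)[jj.ravel()]
        r = corr.ravel()
        keep = ga != gb
        ga, gb, r = ga[keep], gb[keep], r[keep]
        ga, gb = _canonical_pairs(ga, gb)
    table = pd.DataFrame({"gene_a": ga, "gene_b": gb, "r": np.clip(r, -1.0, 1.0)})
    table = table.drop_duplicates(subset=["gene_a", "gene_b"], ignore_index=True)
    table.attrs["condition"] = condition
    return table


@dataclass
class CorrelationHistogram:
    edges: np.ndarray
    counts: np.ndarray
    condition: str | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def histogram_correlations(table: pd.DataFrame,
                           edges: np.ndarray | None = None) -> CorrelationHistogram:
    if len(table) == 0:
        raise ValueError("empty correlation table")
    edges = default_bin_edges() if edges is None else np.asarray(edges, dtype=float)
    counts, _ = np.histogram(table["r"].to_numpy(), bins=edges)
    return CorrelationHistogram(edges=edges, counts=counts,
                                condition=table.attrs.get("condition"))


def histogram_and_chi2(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    edges: np.ndarray | None = None,
) -> dict:
    """Frequency histograms of two correlation tables over the full [-1, 1]
    range plus a chi-square comparison of the binned profiles (the second
    table's proportions, scaled to the first's total, act as expectations).
    """
    edges = default_bin_edges() if edges is None else np.asarray(edges, dtype=float)
    hist_a = histogram_correlations(table_a, edges)
    hist_b = histogram_correlations(table_b, edges)
    stat, dof, p = _chi2_from_counts(hist_a.counts, hist_b.counts)
    return {
        "hist_a": hist_a,
        "hist_b": hist_b,
        "chi2_stat": stat,
        "chi2_dof": dof,
        "chi2_p": p,
    }


def coordination_entropy(hist: CorrelationHistogram | np.ndarray) -> float:
    """Normalized Shannon entropy of a binned correlation distribution.

    S = -sum(p_i ln p_i) / ln(K) over all K bins (0 ln 0 := 0), so S = 1 for
    a uniform histogram and S = 0 for a point mass.
    """
    counts = hist.counts if isinstance(hist, CorrelationHistogram) else np.asarray(hist)
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has no counts")
    k = len(counts)
    if k < 2:
        raise ValueError("entropy needs >= 2 bins")
    p = counts / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / np.log(k))


@dataclass
class BetaFit:
    side: str            # "positive" or "negative"
    alpha: float
    beta: float
    level: float
    threshold: float     # signed: > 0 for the positive side, < 0 for negative
    n: int


@dataclass
class ThresholdPair:
    positive: BetaFit | None
    negative: BetaFit | None

    @property
    def r_pos(self) -> float:
        if self.positive is None:
            raise ValueError("no positive-side threshold")
        return self.positive.threshold

    @property
    def r_neg(self) -> float:
        if self.negative is None:
            raise ValueError("no negative-side threshold")
        return self.negative.threshold

    @classmethod
    def fixed(cls, r_pos: float, r_neg: float | None = None) -> "ThresholdPair":
        """Published fixed cutoffs (e.g. 0.99 for network edges, +/-0.96 for
        strong pairs) in place of a beta fit."""
        r_neg = -r_pos if r_neg is None else r_neg
        if not 0.0 < r_pos < 1.0 or not -1.0 < r_neg < 0.0:
            raise ValueError("fixed thresholds must satisfy -1 < r_neg < 0 < r_pos < 1")
        pos = BetaFit("positive", float("nan"), float("nan"), float("nan"), r_pos, 0)
        neg = BetaFit("negative", float("nan"), float("nan"), float("nan"), r_neg, 0)
        return cls(positive=pos, negative=neg)


_MIN_SIDE_N = 50
_CLIP_EPS = 1e-9


def fit_beta_threshold(table: pd.DataFrame, side: str = "positive",
                       level: float = 0.95) -> BetaFit:
    """Fit a Beta(alpha, beta) law to one side of the correlation
    distribution and return its ``level`` quantile as the strong-correlation
    threshold (negated for the negative side).

    The positive side fits {r : r > 0}; the negative side fits {|r| : r < 0}.
    Maximum likelihood on (0, 1) with support fixed (floc=0, fscale=1);
    values are clipped away from the endpoints by 1e-9 so perfectly
    correlated pairs keep a finite likelihood.
    """
    if side not in ("positive", "negative"):
        raise ValueError("side must be 'positive' or 'negative'")
    r = table["r"].to_numpy()
    data = r[r > 0] if side == "positive" else -r[r < 0]
    if len(data) < _MIN_SIDE_N:
        raise ValueError(
            f"need >= {_MIN_SIDE_N} pairs on the {side} side, got {len(data)}"
        )
    if np.ptp(data) == 0:
        raise ValueError(f"degenerate {side}-side sample (all values equal)")
    data = np.clip(data, _CLIP_EPS, 1.0 - _CLIP_EPS)
    alpha, beta, _, _ = stats.beta.fit(data, floc=0.0, fscale=1.0)
    q = float(stats.beta.ppf(level, alpha, beta))
    threshold = q if side == "positive" else -q
    return BetaFit(side=side, alpha=float(alpha), beta=float(beta),
                   level=level, threshold=threshold, n=len(data))


def fit_beta_thresholds(table: pd.DataFrame, level: float = 0.95) -> ThresholdPair:
    return ThresholdPair(
        positive=fit_beta_threshold(table, "positive", level),
        negative=fit_beta_threshold(table, "negative", level),
    )


@dataclass
class StrongPairSummary:
    n_positive: int
    n_negative: int
    r_avg_positive: float      # NaN when no positive strong pairs
    r_avg_negative: float
    r_pos: float
    r_neg: float
    positive_pairs: pd.DataFrame = field(repr=False)
    negative_pairs: pd.DataFrame = field(repr=False)


def strong_pairs(table: pd.DataFrame, thresholds: ThresholdPair) -> StrongPairSummary:
    """Partition a correlation table into strong-positive (r > r+),
    strong-negative (r < r-) and other pairs, with side-wise counts and
    average correlations."""
    r_pos, r_neg = thresholds.r_pos, thresholds.r_neg
    if not 0.0 < r_pos < 1.0 or not -1.0 < r_neg < 0.0:
        raise ValueError("thresholds must satisfy -1 < r_neg < 0 < r_pos < 1")
    pos = table[table["r"] > r_pos]
    neg = table[table["r"] < r_neg]
    return StrongPairSummary(
        n_positive=len(pos),
        n_negative=len(neg),
        r_avg_positive=float(pos["r"].mean()) if len(pos) else float("nan"),
        r_avg_negative=float(neg["r"].mean()) if len(neg) else float("nan"),
        r_pos=r_pos,
        r_neg=r_neg,
        positive_pairs=pos.reset_index(drop=True),
        negative_pairs=neg.reset_index(drop=True),
    )


def reevaluate_pairs(pairs: pd.DataFrame, other_table: pd.DataFrame) -> dict:
    """Re-measure reference-selected pairs under another condition.

    ``pairs`` carries gene_a/gene_b of pairs selected as strong in a
    reference condition; their correlations are looked up in
    ``other_table`` and summarized, implementing the design where pairs are
    chosen in one state and their average coordination is tracked in
    another.
    """
    merged = pairs[["gene_a", "gene_b"]].merge(
        other_table, on=["gene_a", "gene_b"], how="left"
    )
    found = merged["r"].notna()
    r = merged.loc[found, "r"]
    return {
        "n_requested": len(pairs),
        "n_found": int(found.sum()),
        "r_avg": float(r.mean()) if found.any() else float("nan"),
        "pairs": merged,
    }
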