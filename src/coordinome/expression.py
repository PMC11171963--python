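"""Fold-change statistics, gene-group set algebra, and fold-change clustering.

Works on a genes x samples expression matrix (pandas DataFrame, columns
named ``<condition>_<replicate>``).  Fold changes are base-2 logarithms of
the ratio of condition-mean expressions, so a doubling of activity maps to
+1 and no change maps to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "split_sample_label",
    "condition_columns",
    "matrix_conditions",
    "log2_fold_change",
    "GenePartition",
    "compare_fc_distributions",
    "ClusteringResult",
    "cluster_fold_changes",
]


def split_sample_label(column: str) -> tuple[str, int]:
    """Split ``<condition>_<replicate>`` into its parts.

    The replicate index is the trailing integer; the condition label may
    itself contain underscores.
    """
    cond, _, rep = column.rpartition("_")
    if not cond:
        raise ValueError(f"sample column {column!r} is not <condition>_<replicate>")
    return cond, int(rep)


def condition_columns(matrix: pd.DataFrame, condition: str) -> list:
    cols = [c for c in matrix.columns if split_sample_label(c)[0] == condition]
    if not cols:
        raise KeyError(f"condition {condition!r} not present in matrix")
    return cols


def matrix_conditions(matrix: pd.DataFrame) -> list:
    seen: list = []
    for c in matrix.columns:
        cond = split_sample_label(c)[0]
        if cond not in seen:
            seen.append(cond)
    return seen


def log2_fold_change(matrix: pd.DataFrame, cond_num: str, cond_den: str) -> pd.DataFrame:
    """Per-gene log2 of the ratio of condition mean expressions.

    Genes whose numerator or denominator mean is non-positive are excluded
    and listed in ``result.attrs['excluded']``.
    """
    num = matrix[condition_columns(matrix, cond_num)].mean(axis=1)
    den = matrix[condition_columns(matrix, cond_den)].mean(axis=1)
    valid = (num > 0) & (den > 0)
    excluded = matrix.index[~valid].tolist()
    if excluded:
        warnings.warn(
            f"{len(excluded)} genes with zero/negative condition mean excluded "
            f"from {cond_num} vs {cond_den} fold changes"
        )
    fc = pd.DataFrame(
        {"log2_fc": np.log2(num[valid] / den[valid])},
        index=matrix.index[valid],
    )
    fc.attrs["contrast"] = (cond_num, cond_den)
    fc.attrs["excluded"] = excluded
    return fc


class GenePartition:
    """Named gene sets over a universe of expressed genes.

    Typical sets: the regulated/non-regulated split of the main transition,
    ontology subsets (e.g. nervous-system development), transcription-factor
    genes, or a disease dysregulated/non-dysregulated split.
    """

    def __init__(self, universe: Iterable[str], sets: Mapping[str, Iterable[str]]):
        self.universe = frozenset(universe)
        self.sets: dict = {}
        for name, members in sets.items():
            members = frozenset(members)
            if not members <= self.universe:
                extra = sorted(members - self.universe)[:5]
                raise ValueError(f"set {name!r} contains genes outside the universe: {extra}...")
            self.sets[name] = members

    def __getitem__(self, name: str) -> frozenset:
        try:
            return self.sets[name]
        except KeyError:
            raise KeyError(f"gene set {name!r} is not defined") from None

    def complement(self, name: str) -> frozenset:
        return self.universe - self[name]

    def intersect(self, names: Sequence[str]) -> list:
        """Intersection of the named sets, sorted for stable output."""
        if not names:
            raise ValueError("need at least one set name")
        result = set(self[names[0]])
        for name in names[1:]:
            result &= self[name]
        return sorted(result)


def _chi2_from_counts(obs: np.ndarray, ref: np.ndarray, min_expected: float = 5.0):
    """Chi-square of observed counts against reference-profile expectations.

    Expected counts are the reference proportions scaled to the observed
    total; adjacent bins are pooled until every expected count reaches
    ``min_expected``.  Returns (statistic, dof, p).
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("count vectors must share the same binning")
    if obs.sum() <= 0 or ref.sum() <= 0:
        raise ValueError("empty histogram")
    exp = ref / ref.sum() * obs.sum()
    # pool adjacent bins until expected counts are large enough
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if pooled_exp:
            pooled_obs[-1] += acc_o
            pooled_exp[-1] += acc_e
        else:
            pooled_obs, pooled_exp = [acc_o], [acc_e]
    pooled_obs = np.asarray(pooled_obs)
    pooled_exp = np.asarray(pooled_exp)
    stat = float(np.sum((pooled_obs - pooled_exp) ** 2 / pooled_exp))
    dof = max(len(pooled_obs) - 1, 1)
    p = float(stats.chi2.sf(stat, dof))
    return stat, dof, p


def compare_fc_distributions(
    fc1: pd.Series | np.ndarray,
    fc2: pd.Series | np.ndarray,
    bins: np.ndarray | int | None = 20,
    paired: bool | None = None,
) -> dict:
    """t, Kolmogorov-Smirnov, and binned chi-square comparison of two
    fold-change vectors.

    The t test is paired when both vectors are pandas Series over the same
    aligned gene index (or ``paired=True``), otherwise two-sample.  The KS
    test runs on the unbinned values; the chi-square compares counts on a
    shared binning.
    """
    a = np.asarray(fc1, dtype=float)
    b = np.asarray(fc2, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each fold-change vector needs length >= 3")
    if paired is None:
        paired = (
            isinstance(fc1, pd.Series)
            and isinstance(fc2, pd.Series)
            and len(fc1) == len(fc2)
            and fc1.index.equals(fc2.index)
        )
    out: dict = {"paired": bool(paired)}
    degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
    if degenerate or (paired and np.ptp(a - b) == 0 and len(a) == len(b)):
        out["t_stat"], out["t_p"] = float("nan"), float("nan")
        out["t_defined"] = False
    else:
        if paired:
            t_stat, t_p = stats.ttest_rel(a, b)
        else:
            t_stat, t_p = stats.ttest_ind(a, b)
        out["t_stat"], out["t_p"] = float(t_stat), float(t_p)
        out["t_defined"] = bool(np.isfinite(t_stat))
    ks = stats.ks_2samp(a, b)
    out["ks_stat"], out["ks_p"] = float(ks.statistic), float(ks.pvalue)
    if bins is not None:
        edges = (
            np.histogram_bin_edges(np.concatenate([a, b]), bins=bins)
            if np.isscalar(bins)
            else np.asarray(bins, dtype=float)
        )
        counts_a, _ = np.histogram(a, bins=edges)
        counts_b, _ = np.histogram(b, bins=edges)
        stat, dof, p = _chi2_from_counts(counts_a, counts_b)
        out.update(chi2_stat=stat, chi2_dof=dof, chi2_p=p, bin_edges=edges)
    return out


@dataclass
class ClusteringResult:
    k: int
    labels: pd.Series                 # per-gene cluster label in 1..k
    scores: dict                      # candidate k -> Calinski-Harabasz score
    inertia: float


def cluster_fold_changes(
    points: pd.DataFrame,
    k_range: Sequence[int] = range(2, 13),
    seed: int = 0,
    n_init: int = 10,
) -> ClusteringResult:
    """k-means over per-gene fold-change vectors with the cluster number
    chosen by the Calinski-Harabasz criterion (ties broken toward smaller k).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    k_range = [int(k) for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError("k_range must lie within [2, n_points - 1]")
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("all points identical; clustering is degenerate")
    scores: dict = {}
    fits: dict = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(calinski_harabasz_score(X, labels))
        fits[k] = km
    if not scores:
        raise ValueError("no candidate k produced a valid clustering")
    best_k = min(scores, key=lambda k: (-scores[k], k))
    km = fits[best_k]
    index = points.index if isinstance(points, pd.DataFrame) else pd.RangeIndex(n)
    labels = pd.Series(km.labels_ + 1, index=index, name="cluster")
    return ClusteringResult(k=best_k, labels=labels, scores=scores,
                            inertia=float(km.inertia_))
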