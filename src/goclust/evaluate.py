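"""Cluster evaluation: coexpression and biological-homogeneity indicators.

Two per-cluster indicators are computed, each complemented with a permutation
p-value:

* **CI** (coexpression indicator): the mean of the pairwise Pearson
  correlations between the cluster's genes.  It equals 1 when all genes are
  perfectly positively correlated; with two equal anti-correlated sub-groups
  it reaches its minimum, ``-1/(n-1)`` for even cluster size n and ``-1/n``
  for odd n.

* **BHI** (biological homogeneity indicator): ``1 - V^2`` where ``V`` is
  Cramér's V of the cluster × functions annotation subtable.  Identical
  functional profiles give BHI = 1 (no gene/function association inside the
  cluster); fully gene-private functions give BHI = 0 (maximal association).
  The chi-square bound ``chi2 <= N * (min(rows, cols) - 1)`` keeps BHI in
  [0, 1].

Both indicators depend mechanically on cluster size (CI averages over
n(n-1)/2 pairs; BHI divides by n-1), so raw values are not comparable across
sizes.  The permutation test removes that dependence: the null distribution
is obtained by drawing clusters of the same size without replacement from
the full gene universe, and the p-value is the proportion of null clusters
whose indicator is strictly greater than the observed value.  Because the
null re-uses the real data, it respects the data's distribution.  Singleton
clusters are never tested and are never counted as significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationMatrix
from .expression import ExpressionMatrix
from .partition import GenePartition

__all__ = [
    "coexpression_indicator",
    "biological_homogeneity_indicator",
    "permutation_pvalue",
    "evaluate_partition",
    "ClusterEvaluation",
    "PartitionSummary",
    "NullDistributionCache",
]


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

def _ci_from_corr(corr: np.ndarray, idx: np.ndarray) -> float:
    """Mean off-diagonal correlation of the sub-matrix ``corr[idx, idx]``."""
    n = len(idx)
    sub = corr[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


def coexpression_indicator(G: ExpressionMatrix, cluster: Sequence[str]) -> float:
    """Average pairwise Pearson correlation within a cluster (>= 2 genes)."""
    if len(cluster) < 2:
        raise ValueError("coexpression indicator requires at least 2 genes")
    idx = G.indices(cluster)
    z = G.embedding()[idx]
    corr = np.clip(z @ z.T, -1.0, 1.0)
    return _ci_from_corr(corr, np.arange(len(idx)))


def _bhi_from_subtable(sub: np.ndarray) -> float:
    """BHI from the cluster's rows of the annotation matrix.

    ``sub`` is the n_genes_in_cluster × n_functions 0/1 block; margins are
    those of this subtable.  Functions absent from the cluster contribute
    nothing and are dropped before forming expected counts.
    """
    n = sub.shape[0]
    row = sub.sum(axis=1)
    if (row == 0).any():
        raise ValueError("biological homogeneity undefined for unannotated genes")
    col = sub.sum(axis=0)
    sub = sub[:, col > 0]
    col = col[col > 0]
    total = float(row.sum())
    expected = np.outer(row, col) / total
    chi2 = float(((sub - expected) ** 2 / expected).sum())
    return 1.0 - chi2 / (total * (n - 1))


def biological_homogeneity_indicator(T: AnnotationMatrix, cluster: Sequence[str]) -> float:
    """Similarity of the functional profiles of a cluster's genes (>= 2 genes).

    One minus the squared Cramér's V of the cluster-restricted gene ×
    function table; every cluster gene must carry at least one annotation.
    """
    if len(cluster) < 2:
        raise ValueError("biological homogeneity indicator requires at least 2 genes")
    idx = T.indices(cluster)
    zero = [T.genes[k] for k in idx if T.row_margins[k] == 0]
    if zero:
        raise ValueError("unannotated gene(s) in cluster: " + ", ".join(zero))
    return _bhi_from_subtable(np.asarray(T.values[idx], dtype=float))


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

class NullDistributionCache:
    """Size-indexed null distributions of CI and BHI.

    The null for a cluster of size ``s`` depends on the data and on ``s``
    only, so distributions are drawn once per size and re-used across
    clusters (and across methods, when the cache is shared by a benchmark
    replicate).  Draws are without replacement from the full gene universe.
    """

    def __init__(
        self,
        corr: np.ndarray | None,
        annotation_values: np.ndarray | None,
        B: int,
        rng: np.random.Generator,
    ) -> None:
        self.corr = corr
        self.tvals = (
            None if annotation_values is None else np.asarray(annotation_values, dtype=float)
        )
        self.B = B
        self.rng = rng
        self._ci: dict[int, np.ndarray] = {}
        self._bhi: dict[int, np.ndarray] = {}

    def _draws(self, n_genes: int, size: int) -> np.ndarray:
        # B random subsets of the given size, rows of an index matrix
        keys = self.rng.random((self.B, n_genes))
        return np.argsort(keys, axis=1)[:, :size]

    def ci_null(self, size: int) -> np.ndarray:
        if size not in self._ci:
            if self.corr is None:
                raise ValueError("cache built without expression correlations")
            K = self.corr.shape[0]
            draws = self._draws(K, size)
            Z = np.zeros((K, self.B))
            rows = draws.ravel()
            cols = np.repeat(np.arange(self.B), size)
            Z[rows, cols] = 1.0
            pair_sums = np.einsum("kb,kb->b", Z, self.corr @ Z)
            self._ci[size] = (pair_sums - size) / (size * (size - 1))
        return self._ci[size]

    def bhi_null(self, size: int) -> np.ndarray:
        if size not in self._bhi:
            if self.tvals is None:
                raise ValueError("cache built without annotation values")
            K = self.tvals.shape[0]
            draws = self._draws(K, size)
            vals = np.array([_bhi_from_subtable(self.tvals[d]) for d in draws])
            self._bhi[size] = vals
        return self._bhi[size]


def _pvalue(null: np.ndarray, observed: float) -> float:
    """Proportion of null values strictly greater than the observed one."""
    return float(np.mean(null > observed))


def permutation_pvalue(
    indicator: Callable[..., float],
    context,
    cluster: Sequence[str],
    B: int,
    rng: np.random.Generator,
    gene_universe: Sequence[str] | None = None,
) -> float | None:
    """Generic permutation p-value of an indicator for one cluster.

    ``indicator(context, genes)`` is evaluated on B clusters of the same
    size drawn without replacement from ``gene_universe`` (defaulting to the
    context's genes); the p-value is the proportion of null values strictly
    greater than the observed one.  Returns ``None`` for singletons, which
    are not tested.
    """
    if len(cluster) < 2:
        return None
    if B < 1:
        raise ValueError("B must be >= 1")
    universe = list(gene_universe) if gene_universe is not None else list(context.genes)
    observed = indicator(context, cluster)
    size = len(cluster)
    null = np.empty(B)
    for b in range(B):
        draw = rng.choice(len(universe), size=size, replace=False)
        null[b] = indicator(context, [universe[i] for i in draw])
    return _pvalue(null, observed)


# ---------------------------------------------------------------------------
# Partition-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClusterEvaluation:
    """Per-cluster record: indicator values, p-values and significance flags.

    Singletons carry ``None`` indicators/p-values and are never significant.
    """

    cluster: int
    size: int
    ci: float | None
    bhi: float | None
    ci_pvalue: float | None
    bhi_pvalue: float | None
    significant_ci: bool
    significant_bhi: bool
    significant_both: bool


@dataclass
class PartitionSummary:
    """Partition-level proportions of significant clusters (percent).

    Percentages are computed over *all* clusters of the partition; singleton
    clusters count in the denominator but can never be significant.
    """

    n_clusters: int
    n_singletons: int
    pct_ci: float
    pct_bhi: float
    pct_both: float
    alpha: float
    B: int


def evaluate_partition(
    G: ExpressionMatrix,
    T: AnnotationMatrix,
    partition: GenePartition,
    B: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    corr: np.ndarray | None = None,
    cache: NullDistributionCache | None = None,
) -> tuple[list[ClusterEvaluation], PartitionSummary]:
    """Score every cluster of a partition with CI and BHI permutation tests.

    ``corr`` (precomputed gene correlation matrix) and ``cache`` (shared
    size-indexed null distributions) are optional accelerators; results are
    deterministic given ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if list(partition.genes) != list(G.genes) or list(partition.genes) != list(T.genes):
        raise ValueError("partition, expression and annotation gene universes differ")
    if corr is None:
        corr = G.correlation_matrix()
    if cache is None:
        cache = NullDistributionCache(corr, T.values, B, rng)
    evaluations: list[ClusterEvaluation] = []
    for label, members in enumerate(partition.clusters):
        size = len(members)
        if size < 2:
            evaluations.append(
                ClusterEvaluation(label, size, None, None, None, None, False, False, False)
            )
            continue
        idx = G.indices(members)
        ci = _ci_from_corr(corr, idx)
        bhi = _bhi_from_subtable(np.asarray(T.values[idx], dtype=float))
        ci_p = _pvalue(cache.ci_null(size), ci)
        bhi_p = _pvalue(cache.bhi_null(size), bhi)
        sig_ci = ci_p < alpha
        sig_bhi = bhi_p < alpha
        evaluations.append(
            ClusterEvaluation(
                label, size, ci, bhi, ci_p, bhi_p, sig_ci, sig_bhi, sig_ci and sig_bhi
            )
        )
    n = len(evaluations)
    summary = PartitionSummary(
        n_clusters=n,
        n_singletons=sum(1 for e in evaluations if e.size == 1),
        pct_ci=100.0 * sum(e.significant_ci for e in evaluations) / n,
        pct_bhi=100.0 * sum(e.significant_bhi for e in evaluations) / n,
        pct_both=100.0 * sum(e.significant_both for e in evaluations) / n,
        alpha=alpha,
        B=B,
    )
    return evaluations, summary


def evaluations_to_frame(evaluations: list[ClusterEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in evaluations])
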