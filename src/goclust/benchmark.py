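"""Baseline clusterings and the simulation benchmark driver.

Two comparator methods bracket the annotation-integrated clustering:

* **Heatmap**: plain hierarchical clustering of genes on the correlation
  distance ``1 - r`` (Ward linkage), cut at the target cluster count — the
  gene-side tree of a heatmap.
* **WGCNA-style**: unsigned weighted coexpression network, adjacency
  ``|cor|^beta`` (soft threshold, default beta = 6), topological-overlap
  similarity, average-linkage hierarchical clustering of ``1 - TOM`` cut at
  the target cluster count.

The driver simulates paired expression/annotation datasets, obtains one
partition per method, evaluates every partition with the CI and BHI
permutation tests, and aggregates the percentages of significant clusters
per method and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .annotation import AnnotationMatrix
from .cluster import cluster_genes, distance_matrix
from .decompose import build_t_coexp
from .evaluate import NullDistributionCache, evaluate_partition
from .expression import ExpressionMatrix
from .partition import GenePartition
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "heatmap_clustering",
    "tom_dissimilarity",
    "wgcna_clustering",
    "integration_clustering",
    "BenchmarkResult",
    "run_benchmark",
]


def heatmap_clustering(G: ExpressionMatrix, n_clusters: int) -> GenePartition:
    """Gene-side heatmap partition: Ward tree on correlation distance."""
    if not 2 <= n_clusters <= G.n_genes:
        raise ValueError("n_clusters out of range")
    Z = linkage(pdist(G.embedding()), method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return GenePartition(list(G.genes), labels)


def tom_dissimilarity(corr: np.ndarray, beta: float = 6.0) -> np.ndarray:
    """Topological-overlap dissimilarity 1 - TOM of an unsigned network.

    Adjacency ``a = |corr|^beta`` (zero diagonal); for k != k',
    ``TOM = (sum_u a_ku a_uk' + a_kk') / (min(k_k, k_k') + 1 - a_kk')`` with
    connectivities ``k_i = sum_u a_iu``; ``TOM_kk = 1`` by convention.
    """
    if beta < 1:
        raise ValueError("soft threshold beta must be >= 1")
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    conn = a.sum(axis=1)
    denom = np.minimum.outer(conn, conn) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    d = 1.0 - tom
    np.clip(d, 0.0, None, out=d)
    return 0.5 * (d + d.T)


def wgcna_clustering(
    G: ExpressionMatrix,
    n_clusters: int,
    beta: float = 6.0,
    corr: np.ndarray | None = None,
) -> GenePartition:
    """Coexpression-network partition: average linkage on 1 - TOM."""
    if not 2 <= n_clusters <= G.n_genes:
        raise ValueError("n_clusters out of range")
    if corr is None:
        corr = G.correlation_matrix()
    d = tom_dissimilarity(corr, beta)
    Z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return GenePartition(list(G.genes), labels)


def integration_clustering(
    G: ExpressionMatrix,
    T: AnnotationMatrix,
    n_clusters: int,
    method: str = "hac",
    B: int = 500,
    alpha0: float = 0.10,
    rng: np.random.Generator | None = None,
    corr: np.ndarray | None = None,
    cache: NullDistributionCache | None = None,
) -> GenePartition:
    """Annotation-integrated partition: T_coexp -> chi-square distance ->
    clustering (HAC/Ward by default)."""
    tc, _ = build_t_coexp(G, T, B=B, alpha0=alpha0, rng=rng, corr=corr, cache=cache)
    D = distance_matrix(tc)
    return cluster_genes(D, n_clusters, method=method, rng=rng)


@dataclass
class BenchmarkResult:
    """Tidy per-replicate table and per-(config, method) aggregate means."""

    replicates: pd.DataFrame
    aggregate: pd.DataFrame


def _replicate_rng(seed: int, config_index: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, config_index, replicate])
    )


def run_benchmark(
    configs: Sequence[SimulationConfig],
    n_clusters: int = 20,
    n_replicates: int = 20,
    B: int = 500,
    alpha: float = 0.05,
    alpha0: float = 0.10,
    beta: float = 6.0,
    seed: int = 0,
    methods: Sequence[str] = ("heatmap", "wgcna", "integration"),
) -> BenchmarkResult:
    """Run the simulation benchmark over a grid of configurations.

    For each configuration and replicate a dataset is simulated, each
    method produces an ``n_clusters`` partition, and the partition is scored
    with CI/BHI permutation tests (``B`` draws, threshold ``alpha``).  The
    expression correlation matrix and the size-indexed permutation nulls are
    shared across methods within a replicate.  Fully deterministic given
    ``seed``.
    """
    rows = []
    for ci_idx, config in enumerate(configs):
        for rep in range(n_replicates):
            rng = _replicate_rng(seed, ci_idx, rep)
            sim_seed = int(rng.integers(2**31 - 1))
            data = simulate_dataset(
                SimulationConfig(
                    I=config.I, K=config.K, n_blocks=config.n_blocks,
                    rho_within=config.rho_within, rho_between=config.rho_between,
                    r=config.r, seed=sim_seed,
                )
            )
            G, T = data.G_sim, data.T_sim
            corr = G.correlation_matrix()
            cache = NullDistributionCache(corr, T.values, B, rng)
            partitions = {}
            for m in methods:
                if m == "heatmap":
                    partitions[m] = heatmap_clustering(G, n_clusters)
                elif m == "wgcna":
                    partitions[m] = wgcna_clustering(G, n_clusters, beta=beta, corr=corr)
                elif m == "integration":
                    partitions[m] = integration_clustering(
                        G, T, n_clusters, B=B, alpha0=alpha0,
                        rng=rng, corr=corr, cache=cache,
                    )
                else:
                    raise ValueError(f"unknown method {m!r}")
            for m, part in partitions.items():
                _, summary = evaluate_partition(
                    G, T, part, B=B, alpha=alpha, rng=rng, corr=corr, cache=cache
                )
                rows.append(
                    {
                        "I": config.I, "K": config.K, "r": config.r,
                        "method": m, "replicate": rep,
                        "ci_pct": summary.pct_ci,
                        "bhi_pct": summary.pct_bhi,
                        "both_pct": summary.pct_both,
                        "n_singletons": summary.n_singletons,
                    }
                )
    replicates = pd.DataFrame(rows)
    aggregate = (
        replicates.groupby(["I", "K", "r", "method"], as_index=False)[
            ["ci_pct", "bhi_pct", "both_pct"]
        ].mean()
    )
    return BenchmarkResult(replicates, aggregate)
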