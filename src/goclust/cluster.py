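"""Chi-square gene distance on ``T_coexp`` and the final gene clustering.

The distance between genes k and k' is the chi-square distance between their
row profiles of ``T_coexp``:

    d(k, k') = sum_{j,l} (T_.. / card(K_l^j))
               * (T_kj/T_k. * 1{k in K_l^j} - T_k'j/T_k'. * 1{k' in K_l^j})^2

Two genes are close when they are annotated to the same functions *and* fall
in the same coexpressed sub-clusters of those functions; sharing a function
without being coexpressed contributes a large term.  This is exactly the
between-row distance of the Correspondence Analysis (CA) of ``T_coexp``, a
fact used both for the K-means variant (CA/MDS coordinates realise the
metric in a Euclidean space) and as an independent numerical cross-check.

As printed, the distance is a sum of squares; it is stored squared
(``is_squared=True``) and square-rooted for metric consumers such as Ward
linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .decompose import CoexpAnnotationMatrix
from .partition import GenePartition

__all__ = [
    "GeneDistanceMatrix",
    "chi2_distance",
    "distance_matrix",
    "ca_row_coordinates",
    "cluster_genes",
]


@dataclass
class GeneDistanceMatrix:
    """Symmetric gene × gene distance matrix.

    ``is_squared`` records whether entries are the chi-square sum of squares
    (the printed form) or its square root (the metric satisfying the
    triangle inequality).
    """

    genes: list[str]
    values: np.ndarray
    is_squared: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match gene list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix must be non-negative")
        self.values = np.clip(0.5 * (self.values + self.values.T), 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def sqrt(self) -> "GeneDistanceMatrix":
        if not self.is_squared:
            return self
        return GeneDistanceMatrix(list(self.genes), np.sqrt(self.values), is_squared=False)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def _profiles(tc: CoexpAnnotationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row profiles of T_coexp and the chi-square column weights T_../m_c."""
    row = tc.row_margins.astype(float)
    zero = [g for g, m in zip(tc.genes, tc.row_margins) if m == 0]
    if zero:
        raise ValueError("unannotated gene(s) have no profile: " + ", ".join(zero))
    P = tc.values / row[:, None]
    w = tc.total / tc.col_margins.astype(float)
    return P, w


def chi2_distance(tc: CoexpAnnotationMatrix, gene_k: str, gene_k2: str) -> float:
    """Squared chi-square distance between two genes' T_coexp profiles."""
    P, w = _profiles(tc)
    i = tc.genes.index(gene_k)
    j = tc.genes.index(gene_k2)
    if tc.row_margins[i] == 0 or tc.row_margins[j] == 0:
        raise ValueError("both genes must carry at least one annotation")
    diff = P[i] - P[j]
    return float((w * diff**2).sum())


def distance_matrix(tc: CoexpAnnotationMatrix) -> GeneDistanceMatrix:
    """All-pairs squared chi-square distance between gene profiles.

    Equals the squared Euclidean distance between CA row coordinates of
    ``T_coexp`` when all components are kept.
    """
    P, w = _profiles(tc)
    S = P * np.sqrt(w)
    sq = (S**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (S @ S.T)
    np.clip(d2, 0.0, None, out=d2)
    return GeneDistanceMatrix(list(tc.genes), d2, is_squared=True)


def ca_row_coordinates(tc: CoexpAnnotationMatrix, tol: float = 1e-12) -> np.ndarray:
    """Principal row coordinates of the Correspondence Analysis of T_coexp.

    All non-trivial components are kept, so pairwise squared Euclidean
    distances between rows reproduce :func:`distance_matrix` exactly (up to
    numerical error).
    """
    N = tc.values.astype(float)
    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        raise ValueError("unannotated genes have no CA coordinates")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sing, _ = np.linalg.svd(S, full_matrices=False)
    keep = sing > tol * sing.max() if sing.size else np.array([], dtype=bool)
    return (U[:, keep] * sing[keep]) / np.sqrt(r)[:, None]


def _mds_embedding(d2: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates from squared distances.

    Exact for Euclidean-embeddable matrices such as the chi-square distance;
    the embedding agrees with the CA row coordinates up to rotation and
    translation, which K-means is invariant to.
    """
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(Bmat)
    keep = vals > tol * max(vals.max(), 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


def cluster_genes(
    D: GeneDistanceMatrix,
    n_clusters: int,
    method: str = "hac",
    rng: np.random.Generator | None = None,
    n_restarts: int = 20,
) -> GenePartition:
    """Cluster genes from the chi-square distance matrix.

    ``hac``: Ward linkage on the square-rooted distances, cut at
    ``n_clusters``.  ``kmeans``: K-means in the (MDS-reconstructed) CA
    coordinate space with ``n_restarts`` seeded restarts, best inertia kept.
    Singleton clusters are permitted.
    """
    n = len(D.genes)
    if not 2 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in [2, {n}]")
    if method == "hac":
        metric = D.sqrt()
        Z = linkage(metric.condensed(), method="ward")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif method == "kmeans":
        if rng is None:
            rng = np.random.default_rng()
        d2 = D.values if D.is_squared else D.values**2
        X = _mds_embedding(d2)
        km = KMeans(
            n_clusters=n_clusters,
            n_init=n_restarts,
            random_state=int(rng.integers(2**31 - 1)),
        )
        labels = km.fit_predict(X)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")
    return GenePartition(list(D.genes), np.asarray(labels))
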