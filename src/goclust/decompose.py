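"""Decomposition of biological functions into coexpressed biological functions.

A biological function is the set of genes annotated to it.  Those genes need
not be coexpressed: the function may mix genes activated by unrelated
processes.  This module restricts each function to coexpressed sub-clusters,
turning the gene × function matrix T into the expanded gene ×
coexpressed-function matrix ``T_coexp``:

* **step 0** — test whether the function's genes are globally coexpressed:
  the coexpression indicator of the gene set is compared with size-matched
  random gene sets; if the permutation p-value is below ``alpha0`` (default
  10%), the function is kept whole as a single column;
* **steps 1–3** — otherwise the function's genes are clustered on the
  correlation distance ``1 - r`` (Ward linkage), the tree is cut at the
  partition with the highest relative loss of intra-cluster inertia, and the
  function's column is split into one dummy column per coexpressed
  sub-cluster.

The resulting columns of ``T_coexp`` carry the general term
``T_kj * 1{k in K_l^j}``.  Per function, the sub-cluster cardinalities sum to
the original column margin T_.j; row margins and the grand total are those
of T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .annotation import AnnotationMatrix
from .evaluate import NullDistributionCache, _ci_from_corr, _pvalue
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionPartition",
    "CoexpAnnotationMatrix",
    "cut_tree_by_relative_inertia",
    "test_function_coexpression",
    "build_t_coexp",
    "write_t_coexp",
    "write_partition_report",
]


@dataclass
class FunctionPartition:
    """Partition of one function's gene set into coexpressed sub-clusters."""

    function: str
    sub_clusters: list[list[str]]
    coexpressed_whole: bool
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("a function partition needs at least one sub-cluster")
        members = [g for c in self.sub_clusters for g in c]
        if len(members) != len(set(members)):
            raise ValueError("sub-clusters of a function must be disjoint")
        if self.coexpressed_whole and self.L != 1:
            raise ValueError("a whole coexpressed function has exactly one sub-cluster")

    @property
    def L(self) -> int:
        return len(self.sub_clusters)


@dataclass
class CoexpAnnotationMatrix:
    """Gene × coexpressed-function binary matrix ``T_coexp``.

    ``columns[c] = (function, l)`` tags column ``c`` with its parent function
    and sub-cluster index; ``col_margins[c] = card(K_l^j)``.  Row margins and
    total are inherited from (and validated against) the source T.
    """

    genes: list[str]
    columns: list[tuple[str, int]]
    values: np.ndarray
    row_margins: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_margins: np.ndarray = field(default=None)  # type: ignore[assignment]
    total: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("T_coexp entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.genes), len(self.columns)):
            raise ValueError("T_coexp shape does not match identifiers")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicated (function, sub-cluster) column tags")
        if self.row_margins is None:
            self.row_margins = self.values.sum(axis=1, dtype=int)
        if self.col_margins is None:
            self.col_margins = self.values.sum(axis=0, dtype=int)
        if self.total is None:
            self.total = int(self.values.sum())
        if not np.array_equal(self.values.sum(axis=0, dtype=int), self.col_margins):
            raise ValueError("stored column margins inconsistent with values")
        if not np.array_equal(self.values.sum(axis=1, dtype=int), self.row_margins):
            raise ValueError("stored row margins inconsistent with values")
        if int(self.values.sum()) != self.total:
            raise ValueError("stored total inconsistent with values")

    @property
    def functions(self) -> list[str]:
        """Parent functions in column order, without repetition."""
        seen: list[str] = []
        for f, _ in self.columns:
            if not seen or seen[-1] != f:
                seen.append(f)
        return seen

    @property
    def column_labels(self) -> list[str]:
        return [f"{f}::{l}" for f, l in self.columns]

    @classmethod
    def from_annotation(cls, T: AnnotationMatrix) -> "CoexpAnnotationMatrix":
        """Identity decomposition: every function is one whole column."""
        return cls(list(T.genes), [(f, 1) for f in T.functions], T.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.column_labels)


# ---------------------------------------------------------------------------
# Tree cutting by relative loss of inertia
# ---------------------------------------------------------------------------

def _partition_inertia(X: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of squared deviations from the cluster centroid."""
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def cut_tree_by_relative_inertia(
    Z: np.ndarray, X: np.ndarray, L_max: int
) -> np.ndarray:
    """Cut a hierarchical tree at the number of clusters with the highest
    relative loss of intra-cluster inertia.

    ``Z`` is a scipy linkage matrix over the n rows of ``X`` (the coordinates
    the tree was built on).  For each candidate partition size L the sum of
    intra-cluster inertias W(L) is computed; the returned partition is the
    one whose refinement step produced the largest relative drop,
    ``argmax_L (W(L-1) - W(L)) / W(L-1)`` over L in {2, ..., L_max}, ties
    broken toward the smaller L.  With n = 2 the split is forced.
    """
    n = X.shape[0]
    if n < 2:
        raise ValueError("cannot cut a tree over fewer than 2 items")
    L_max = int(min(max(L_max, 2), n))
    if n == 2:
        return np.array([0, 1])
    W = {1: _partition_inertia(X, np.zeros(n, dtype=int))}
    labels_at = {}
    for L in range(2, L_max + 1):
        labels = fcluster(Z, t=L, criterion="maxclust")
        labels_at[L] = labels
        W[L] = _partition_inertia(X, labels)
    best_L, best_loss = 2, -np.inf
    for L in range(2, L_max + 1):
        prev = W[L - 1]
        loss = (prev - W[L]) / prev if prev > 1e-12 else 0.0
        if loss > best_loss + 1e-12:
            best_L, best_loss = L, loss
    return labels_at[best_L] - 1


# ---------------------------------------------------------------------------
# Step 0: coexpression filter on whole functions
# ---------------------------------------------------------------------------

def test_function_coexpression(
    G: ExpressionMatrix,
    function_genes,
    B: int = 500,
    alpha0: float = 0.10,
    rng: np.random.Generator | None = None,
    corr: np.ndarray | None = None,
    cache: NullDistributionCache | None = None,
) -> tuple[bool, float]:
    """Test whether a function's gene set is globally coexpressed.

    The coexpression indicator of the gene set is compared with B
    size-matched gene sets drawn without replacement from all genes of G;
    the function is declared coexpressed when the permutation p-value is
    below ``alpha0``.
    """
    genes = list(function_genes)
    if len(genes) < 2:
        raise ValueError("coexpression test requires at least 2 genes")
    if rng is None:
        rng = np.random.default_rng()
    if corr is None:
        corr = G.correlation_matrix()
    if cache is None:
        cache = NullDistributionCache(corr, None, B, rng)
    observed = _ci_from_corr(corr, G.indices(genes))
    p = _pvalue(cache.ci_null(len(genes)), observed)
    return p < alpha0, p


# ---------------------------------------------------------------------------
# Building T_coexp
# ---------------------------------------------------------------------------

def build_t_coexp(
    G: ExpressionMatrix,
    T: AnnotationMatrix,
    B: int = 500,
    alpha0: float = 0.10,
    l_max: int = 10,
    rng: np.random.Generator | None = None,
    corr: np.ndarray | None = None,
    cache: NullDistributionCache | None = None,
) -> tuple[CoexpAnnotationMatrix, list[FunctionPartition]]:
    """Decompose every function of T into coexpressed biological functions.

    Functions passing the step-0 coexpression test (p < ``alpha0``) are kept
    as single columns; the others are split by Ward clustering on the
    correlation distance, cut by relative loss of inertia with at most
    ``min(l_max, card(K^j) - 1)`` sub-clusters.  Setting ``alpha0 >= 1``
    keeps every function whole, so ``T_coexp`` equals T.

    Sub-clusters are ordered by decreasing size (ties by first gene
    position) and numbered l = 1..L_j after ordering.  Deterministic given
    ``rng``.
    """
    if list(G.genes) != list(T.genes):
        raise ValueError("expression and annotation gene universes differ")
    if T.n_functions == 0:
        raise ValueError("empty annotation matrix")
    small = [f for f, m in zip(T.functions, T.col_margins) if m < 2]
    if small:
        raise ValueError(
            "function(s) with fewer than 2 genes (apply filter_functions): "
            + ", ".join(small[:10])
        )
    if rng is None:
        rng = np.random.default_rng()
    if corr is None:
        corr = G.correlation_matrix()
    if cache is None:
        cache = NullDistributionCache(corr, None, B, rng)
    embedding = G.embedding()

    partitions: list[FunctionPartition] = []
    col_tags: list[tuple[str, int]] = []
    col_vectors: list[np.ndarray] = []
    for j, function in enumerate(T.functions):
        idx = np.flatnonzero(T.values[:, j])
        genes_j = [T.genes[k] for k in idx]
        if alpha0 >= 1.0:
            coexp, p = True, None
        else:
            coexp, p = test_function_coexpression(
                G, genes_j, B=B, alpha0=alpha0, rng=rng, corr=corr, cache=cache
            )
        if coexp:
            partitions.append(FunctionPartition(function, [genes_j], True, p))
            col_tags.append((function, 1))
            col_vectors.append(T.values[:, j].astype(np.int8))
            continue
        X = embedding[idx]
        labels = _split_gene_set(X, l_max)
        groups = [idx[labels == lab] for lab in np.unique(labels)]
        groups.sort(key=lambda g: (-len(g), int(g.min())))
        subs = [[T.genes[k] for k in g] for g in groups]
        partitions.append(FunctionPartition(function, subs, False, p))
        for l, g in enumerate(groups, start=1):
            col = np.zeros(T.n_genes, dtype=np.int8)
            col[g] = 1
            col_tags.append((function, l))
            col_vectors.append(col)

    tc = CoexpAnnotationMatrix(list(T.genes), col_tags, np.column_stack(col_vectors))
    # Figure-2 structural invariants, asserted on every build
    if not np.array_equal(tc.row_margins, T.row_margins) or tc.total != T.total:
        raise AssertionError("T_coexp row margins/total differ from T")
    sums: dict[str, int] = {}
    for (f, _), m in zip(tc.columns, tc.col_margins):
        sums[f] = sums.get(f, 0) + int(m)
    for f, m in zip(T.functions, T.col_margins):
        if sums.get(f) != int(m):
            raise AssertionError(f"sub-cluster cardinalities of {f!r} do not sum to T_.j")
    return tc, partitions


def _split_gene_set(X: np.ndarray, l_max: int) -> np.ndarray:
    """Ward tree + relative-inertia cut over the rows of X (n >= 2)."""
    n = X.shape[0]
    if n == 2:
        return np.array([0, 1])
    Z = linkage(pdist(X), method="ward")
    return cut_tree_by_relative_inertia(Z, X, min(l_max, n - 1))


def write_t_coexp(tc: CoexpAnnotationMatrix, path) -> None:
    tc.to_frame().to_csv(path, sep="\t", index_label="gene")


def write_partition_report(partitions: list[FunctionPartition], path) -> None:
    rows = []
    for p in partitions:
        for l, genes in enumerate(p.sub_clusters, start=1):
            rows.append(
                {
                    "function": p.function,
                    "L": p.L,
                    "step0_pvalue": p.p_value,
                    "coexpressed_whole": p.coexpressed_whole,
                    "sub_cluster": l,
                    "size": len(genes),
                    "genes": ";".join(genes),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
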