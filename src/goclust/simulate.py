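"""Co-simulation of expression data and GO-like annotations.

The generator produces the paired inputs used by the benchmark:

* **Expression** ``G_sim``: K genes × I samples drawn from a multivariate
  Gaussian whose correlation matrix is block-diagonal — ``rho_within``
  inside each planted block of coexpressed genes, ``rho_between``
  (default 0) elsewhere.
* **Structured annotations** ``T_e``: a classification tree of the genes is
  built from the correlation distance of their simulated expression
  profiles; every internal node except the root becomes a biological
  function whose gene set is the node's leaves.  The nesting of tree nodes
  mimics the hierarchical structure of GO, and genes with similar expression
  mechanically share similar functional profiles.
* **Random annotations** ``T_r``: ``r`` copies of ``T_e`` whose rows are
  permuted independently within each column.  Column margins — the
  specificity of each function — are conserved exactly; any association with
  the expression structure is destroyed.  ``r`` is the *intensity of
  randomness*: the simulated annotation matrix ``T_sim = [T_e | T_r]``
  contains r times more random than structured functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .annotation import AnnotationMatrix
from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_expression",
    "simulate_structured_annotations",
    "simulate_random_annotations",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults follow the small benchmark configuration: 10 samples, 300
    genes in 20 equally sized planted blocks with within-block correlation
    0.85, independent blocks, and one random annotation copy (r = 1).
    """

    I: int = 10
    K: int = 300
    n_blocks: int = 20
    rho_within: float = 0.85
    rho_between: float = 0.0
    r: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I < 3 or self.K < 3:
            raise ValueError("need at least 3 samples and 3 genes")
        if not 1 <= self.n_blocks <= self.K:
            raise ValueError("n_blocks must lie in [1, K]")
        # rho_between == rho_within (e.g. both 0) degenerates to no block
        # structure, which the unstructured-data checks rely on
        if not 0.0 <= self.rho_between <= self.rho_within <= 1.0:
            raise ValueError("require 0 <= rho_between <= rho_within <= 1")
        if self.r < 1:
            raise ValueError("randomness intensity r must be >= 1")

    def block_sizes(self) -> np.ndarray:
        base, extra = divmod(self.K, self.n_blocks)
        return np.array([base + (b < extra) for b in range(self.n_blocks)])


@dataclass
class SimulatedDataset:
    """Paired simulated inputs with ground truth and provenance."""

    G_sim: ExpressionMatrix
    T_sim: AnnotationMatrix
    block_truth: np.ndarray
    column_provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_struct = self.column_provenance.count("structured")
        n_rand = self.column_provenance.count("random")
        if n_struct + n_rand != self.T_sim.n_functions:
            raise ValueError("provenance tags do not cover all functions")


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Block-correlated Gaussian expression with planted coexpression blocks.

    Gene g in block b is ``sqrt(rho_b)*h + sqrt(rho_w - rho_b)*f_b +
    sqrt(1 - rho_w)*eps`` with independent standard normal factors, giving
    population correlation ``rho_within`` within blocks and ``rho_between``
    across blocks.  Returns the matrix and the planted block label per gene.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = config.block_sizes()
    truth = np.repeat(np.arange(config.n_blocks), sizes)
    shared = rng.standard_normal((config.I, 1))
    factors = rng.standard_normal((config.I, config.n_blocks))
    noise = rng.standard_normal((config.I, config.K))
    a = np.sqrt(config.rho_between)
    b = np.sqrt(config.rho_within - config.rho_between)
    c = np.sqrt(1.0 - config.rho_within)
    X = a * shared + b * factors[:, truth] + c * noise
    genes = [f"g{k:04d}" for k in range(config.K)]
    samples = [f"s{i:02d}" for i in range(config.I)]
    return ExpressionMatrix(genes, samples, X.T), truth


def _tree_node_leafsets(Z: np.ndarray, n: int) -> list[np.ndarray]:
    """Leaf index sets of the internal nodes of a linkage tree, in merge
    order, excluding the root."""
    sets: dict[int, np.ndarray] = {k: np.array([k]) for k in range(n)}
    nodes: list[np.ndarray] = []
    for m, (a, b, *_rest) in enumerate(Z):
        merged = np.sort(np.concatenate([sets[int(a)], sets[int(b)]]))
        sets[n + m] = merged
        nodes.append(merged)
    return nodes[:-1]  # drop the root (all genes): an all-ones column is uninformative


def simulate_structured_annotations(G_sim: ExpressionMatrix) -> AnnotationMatrix:
    """Tree-derived annotations: one function per internal tree node.

    A Ward classification tree of the genes is built from the correlation
    distance of their expression profiles; each internal node except the
    root becomes a function annotated to the node's leaves.  A binary tree
    over K genes yields K - 2 columns, each column margin equal to the
    number of leaves under the node.
    """
    if G_sim.n_genes < 3:
        raise ValueError("need at least 3 genes to build a classification tree")
    Z = linkage(pdist(G_sim.embedding()), method="ward")
    nodes = _tree_node_leafsets(Z, G_sim.n_genes)
    values = np.zeros((G_sim.n_genes, len(nodes)), dtype=np.int8)
    for j, leaves in enumerate(nodes):
        values[leaves, j] = 1
    functions = [f"node{j:04d}" for j in range(len(nodes))]
    return AnnotationMatrix(list(G_sim.genes), functions, values)


def simulate_random_annotations(
    T_e: AnnotationMatrix, r: int, rng: np.random.Generator
) -> AnnotationMatrix:
    """r row-permuted copies of the structured annotations.

    Each output column is an independent permutation of its source column:
    column margins are conserved exactly, row margins are not, and the
    permuted columns carry no association with the expression structure.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    K, J = T_e.values.shape
    values = np.empty((K, r * J), dtype=np.int8)
    functions: list[str] = []
    for copy in range(r):
        for j in range(J):
            perm = rng.permutation(K)
            values[:, copy * J + j] = T_e.values[perm, j]
            functions.append(f"rnd{copy}_{T_e.functions[j]}")
    return AnnotationMatrix(list(T_e.genes), functions, values)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full co-simulation: expression, structured + random annotations.

    Deterministic given ``config.seed``; provenance tags record whether
    each function column is structured or random.
    """
    rng = np.random.default_rng(config.seed)
    G_sim, truth = simulate_expression(config, rng)
    T_e = simulate_structured_annotations(G_sim)
    T_r = simulate_random_annotations(T_e, config.r, rng)
    values = np.concatenate([T_e.values, T_r.values], axis=1)
    T_sim = AnnotationMatrix(
        list(G_sim.genes), list(T_e.functions) + list(T_r.functions), values
    )
    provenance = ["structured"] * T_e.n_functions + ["random"] * T_r.n_functions
    return SimulatedDataset(G_sim, T_sim, truth, provenance)
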