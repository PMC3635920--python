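"""Encoding of gene / biological-function associations.

Associations between genes and biological functions (typically Gene Ontology
"Biological Process" terms) are encoded in a binary matrix T with one row per
gene and one column per function: ``T[k, j] = 1`` iff gene ``k`` is annotated
to function ``j``.  A row is the gene's *functional profile*; a column is the
gene set of a function.  The margins T_k. (functions per gene), T_.j (genes
per function) and the grand total T_.. drive the chi-square geometry used
downstream, so they are stored and validated explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMatrix",
    "build_annotation_matrix",
    "propagate_ancestors",
    "filter_functions",
    "read_gene_term_pairs",
    "read_gaf",
    "read_obo_dag",
    "write_annotation_matrix",
    "read_annotation_matrix",
]


@dataclass
class AnnotationMatrix:
    """Binary gene × function matrix with explicit margins.

    ``row_margins[k] = T_k.``, ``col_margins[j] = T_.j``, ``total = T_..``.
    Genes with an all-zero row (no annotation) are retained — dropping them
    would desynchronise gene indices with the expression matrix — but flagged
    through :attr:`unannotated_genes`; distance computations reject them.
    """

    genes: list[str]
    functions: list[str]
    values: np.ndarray
    row_margins: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_margins: np.ndarray = field(default=None)  # type: ignore[assignment]
    total: int = field(default=None)  # type: ignore[assignment]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("annotation matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.genes), len(self.functions)):
            raise ValueError("annotation matrix shape does not match identifiers")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicated gene identifiers")
        if len(set(self.functions)) != len(self.functions):
            raise ValueError("duplicated function identifiers")
        if self.row_margins is None:
            self.row_margins = self.values.sum(axis=1, dtype=int)
        if self.col_margins is None:
            self.col_margins = self.values.sum(axis=0, dtype=int)
        if self.total is None:
            self.total = int(self.values.sum())
        self.validate_margins()
        self._index = {g: k for k, g in enumerate(self.genes)}

    def validate_margins(self) -> None:
        """Recompute margins from the values and compare with the stored ones."""
        rm = self.values.sum(axis=1, dtype=int)
        cm = self.values.sum(axis=0, dtype=int)
        if not (
            np.array_equal(rm, self.row_margins)
            and np.array_equal(cm, self.col_margins)
            and int(rm.sum()) == self.total == int(cm.sum())
        ):
            raise ValueError("stored margins inconsistent with matrix values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_functions(self) -> int:
        return len(self.functions)

    @property
    def unannotated_genes(self) -> list[str]:
        return [g for g, m in zip(self.genes, self.row_margins) if m == 0]

    def indices(self, genes: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} absent from annotation matrix")

    def function_genes(self, function: str) -> list[str]:
        """K^j: the genes annotated to a function."""
        j = self.functions.index(function)
        return [g for g, v in zip(self.genes, self.values[:, j]) if v]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.functions)


def build_annotation_matrix(
    associations: Iterable[tuple[str, str]], gene_universe: Sequence[str]
) -> AnnotationMatrix:
    """Build T from (gene, function) pairs over a fixed ordered gene universe.

    Duplicate pairs collapse to a single 1.  Functions appear in first-seen
    order.  An association whose gene is outside the universe is an error
    (the offending gene is named), as is an empty association list.
    """
    gene_universe = list(gene_universe)
    if not gene_universe:
        raise ValueError("gene universe is empty")
    gene_idx = {g: k for k, g in enumerate(gene_universe)}
    functions: list[str] = []
    func_idx: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_assoc = 0
    for gene, function in associations:
        n_assoc += 1
        if gene not in gene_idx:
            raise ValueError(f"association references gene {gene!r} outside the gene universe")
        if function not in func_idx:
            func_idx[function] = len(functions)
            functions.append(function)
        pairs.add((gene_idx[gene], func_idx[function]))
    if n_assoc == 0:
        raise ValueError("no gene-function associations provided")
    values = np.zeros((len(gene_universe), len(functions)), dtype=np.int8)
    rows, cols = zip(*pairs)
    values[list(rows), list(cols)] = 1
    return AnnotationMatrix(gene_universe, functions, values)


def propagate_ancestors(
    associations: Iterable[tuple[str, str]],
    dag: Mapping[str, Iterable[str]],
) -> list[tuple[str, str]]:
    """Augment associations with the transitive ancestors of each term.

    ``dag`` maps a term to its direct parents.  When a gene is annotated to a
    term it becomes annotated to every ancestor of that term as well; the
    operation is idempotent.  Terms absent from the dag are passed through
    unchanged (leaves of unknown lineage) and logged.  A cycle is an error.
    """
    graph = nx.DiGraph()
    for child, parents in dag.items():
        graph.add_node(child)
        for p in parents:
            graph.add_edge(child, p)
    if graph.number_of_nodes() and not nx.is_directed_acyclic_graph(graph):
        raise ValueError("term hierarchy contains a cycle")
    closure: dict[str, set[str]] = {}
    unknown: set[str] = set()
    out: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()

    def add(gene: str, term: str) -> None:
        if (gene, term) not in seen:
            seen.add((gene, term))
            out.append((gene, term))

    for gene, term in associations:
        add(gene, term)
        if term not in graph:
            unknown.add(term)
            continue
        if term not in closure:
            closure[term] = nx.descendants(graph, term)  # edges point child -> parent
        for anc in sorted(closure[term]):
            add(gene, anc)
    if unknown:
        logger.info(
            "%d term(s) absent from the hierarchy, passed through unchanged: %s",
            len(unknown), ", ".join(sorted(unknown)[:10]),
        )
    return out


def filter_functions(T: AnnotationMatrix, min_genes: int = 2) -> AnnotationMatrix:
    """Drop functions annotated to fewer than ``min_genes`` genes.

    A single-gene function contributes nothing to between-gene similarity and
    cannot be decomposed, hence the default threshold of 2.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    keep = np.flatnonzero(T.col_margins >= min_genes)
    if keep.size == 0:
        raise ValueError(
            f"no function has at least {min_genes} annotated genes; "
            "lower the min_genes threshold"
        )
    return AnnotationMatrix(
        list(T.genes), [T.functions[j] for j in keep], T.values[:, keep]
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gene_term_pairs(path) -> list[tuple[str, str]]:
    """Two-column delimited text: gene<TAB>term (comma/semicolon accepted)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="!",
                     usecols=[0, 1], dtype=str)
    df = df.dropna()
    return [(str(g), str(t)) for g, t in df.itertuples(index=False)]


def read_gaf(path, exclude_evidence: Sequence[str] | None = None) -> list[tuple[str, str]]:
    """GAF 2.x reader: columns 2 (DB object symbol) and 5 (GO ID).

    ``exclude_evidence`` drops rows whose evidence code (column 7) is listed,
    e.g. ``["IEA"]`` to ignore electronically inferred annotations.
    """
    excluded = set(exclude_evidence or ())
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"malformed GAF line: {line!r}")
            if fields[6] in excluded:
                continue
            pairs.append((fields[1], fields[4]))
    if not pairs:
        raise ValueError(f"no usable annotation rows in {path}")
    return pairs


def read_obo_dag(path, relations: Sequence[str] = ("is_a",)) -> dict[str, list[str]]:
    """Parse an OBO 1.2 ontology into a term -> direct parents mapping.

    Only the edge types in ``relations`` are followed; the default keeps
    ``is_a`` edges, ``part_of`` can be added explicitly.
    """
    import obonet

    graph = obonet.read_obo(path)
    wanted = set(relations)
    dag: dict[str, list[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key in wanted:
            dag.setdefault(child, []).append(parent)
    return dag


def write_annotation_matrix(T: AnnotationMatrix, path) -> None:
    T.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_annotation_matrix(path) -> AnnotationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AnnotationMatrix(
        [str(g) for g in df.index], [str(f) for f in df.columns], df.values
    )
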