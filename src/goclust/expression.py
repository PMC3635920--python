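"""Expression matrices and correlation-based gene distances.

The central object is :class:`ExpressionMatrix`, a validated gene × sample
matrix of real-valued expression measurements (genes as rows).  All
correlation computations in the package use the Pearson coefficient with the
population (1/I) normalisation; the correlation-based distance between two
genes is ``d = 1 - r``, which ranges over [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "correlation_distance_matrix",
    "read_expression",
    "write_expression",
]


@dataclass
class ExpressionMatrix:
    """Gene × sample expression matrix.

    Parameters
    ----------
    genes : ordered gene identifiers (rows).
    samples : ordered sample identifiers (columns).
    values : real matrix of shape ``(len(genes), len(samples))``; entry
        ``values[k, i]`` is the expression of gene ``k`` in sample ``i``.

    Genes with constant expression are rejected at construction: a zero
    standard deviation makes every correlation involving the gene undefined.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicated gene identifiers in expression matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample identifiers in expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")
        sd = self.values.std(axis=1)
        constant = [g for g, s in zip(self.genes, sd) if s == 0.0]
        if constant:
            raise ValueError(
                "constant expression profile for gene(s): " + ", ".join(constant)
            )
        self._index = {g: k for k, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        """Number of samples I."""
        return len(self.samples)

    def indices(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices for a sequence of gene identifiers."""
        try:
            return np.array([self._index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} absent from expression matrix")

    def standardized(self) -> np.ndarray:
        """Row-standardised matrix ``(x - mean) / sd`` with the 1/I sd."""
        mean = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        return (self.values - mean) / sd

    def embedding(self) -> np.ndarray:
        """Unit-norm row embedding whose squared Euclidean distance is
        ``2 * (1 - r)``, i.e. twice the correlation distance."""
        return self.standardized() / np.sqrt(self.n_samples)

    def correlation_matrix(self) -> np.ndarray:
        """Full gene × gene Pearson correlation matrix."""
        z = self.embedding()
        c = z @ z.T
        np.clip(c, -1.0, 1.0, out=c)
        np.fill_diagonal(c, 1.0)
        return c

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.indices(genes)
        return ExpressionMatrix(list(genes), list(self.samples), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def correlation_distance_matrix(
    G: ExpressionMatrix, gene_subset: Sequence[str] | None = None
) -> np.ndarray:
    """Correlation distance ``d(k, k') = 1 - r(k, k')`` between genes.

    Returns a symmetric matrix with zero diagonal and values in [0, 2].
    ``gene_subset`` restricts to (and orders by) the given genes.
    """
    if gene_subset is None:
        idx = np.arange(G.n_genes)
    else:
        if len(gene_subset) < 2:
            raise ValueError("need at least two genes for a distance matrix")
        idx = G.indices(gene_subset)
    if G.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    z = G.embedding()[idx]
    d = 1.0 - z @ z.T
    np.clip(d, 0.0, 2.0, out=d)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def read_expression(path) -> ExpressionMatrix:
    """Read a delimited expression file: first column gene IDs, header row of
    sample IDs.  Delimiter is sniffed from tab/comma/semicolon.

    Rejects non-numeric cells, missing values, constant genes (named in the
    error) and conflicting duplicate gene rows; identical duplicate rows are
    collapsed.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.empty:
        raise ValueError(f"empty expression file: {path}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if df.isna().any().any() or len(bad):
        nn = df.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(nn.isna().values)[0]
        raise ValueError(
            f"non-numeric or missing value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique()
        for g in dup:
            rows = df.loc[[g]].drop_duplicates()
            if len(rows) > 1:
                raise ValueError(f"conflicting duplicate rows for gene {g!r}")
        df = df[~df.index.duplicated(keep="first")]
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.values.astype(float)
    )


def write_expression(G: ExpressionMatrix, path) -> None:
    G.to_frame().to_csv(path, sep="\t", index_label="gene")
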