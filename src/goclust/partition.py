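"""Gene partitions (clusterings) shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenePartition"]


@dataclass
class GenePartition:
    """A partition of an ordered gene list into disjoint clusters.

    ``labels[k]`` is the (integer) cluster of gene ``k``.  Labels are
    canonicalised to 0..n_clusters-1 in order of first appearance, so two
    partitions that group genes identically compare equal regardless of the
    original label values.
    """

    genes: list[str]
    labels: np.ndarray
    _clusters: list[list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != (len(self.genes),):
            raise ValueError("one label per gene required")
        _, canonical = np.unique(labels, return_inverse=True)
        # renumber by first appearance for stable, input-order output
        order = {}
        relabeled = np.empty(len(labels), dtype=int)
        for k, lab in enumerate(canonical):
            if lab not in order:
                order[lab] = len(order)
            relabeled[k] = order[lab]
        self.labels = relabeled
        clusters: list[list[str]] = [[] for _ in range(relabeled.max() + 1)]
        for g, lab in zip(self.genes, relabeled):
            clusters[lab].append(g)
        self._clusters = clusters

    @property
    def n_clusters(self) -> int:
        return len(self._clusters)

    @property
    def clusters(self) -> list[list[str]]:
        """Gene lists per cluster, indexed by canonical label."""
        return [list(c) for c in self._clusters]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self._clusters])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "cluster": self.labels})
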