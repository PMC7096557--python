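"""Cell type specificity of genes: minimum fold change of mean CPM.

The specificity of gene g in cell type c is the minimum, over every other
cell type r, of the ratio of mean CPM in c to mean CPM in r. A gene that
is expressed well above every other cell type in exactly one type scores
high in that type; a uniformly expressed gene scores about 1 everywhere.
A pseudocount epsilon (default 1 CPM) is added to both means so the ratio
stays finite when a reference type does not express the gene at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SpecificityMatrix:
    """Genes x cell types matrix of min-fold-change specificity values."""

    values: pd.DataFrame  # index genes, columns cell types
    n_per_type: dict[str, int]
    pseudocount: float

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class MarkerPanel:
    """Top-n cell type-specific genes for one cell type, best first."""

    cell_type: str
    genes: list[str]
    n_requested: int

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.genes) + "\n")


def compute_specificity(
    cpm_matrix: np.ndarray,
    genes,
    class_labels,
    pseudocount: float = 1.0,
    exclude_labels: tuple[str, ...] = (),
) -> SpecificityMatrix:
    """Min-fold-change specificity of each gene in each cell type.

    Parameters
    ----------
    cpm_matrix
        Gene x nucleus CPM matrix.
    class_labels
        Per-nucleus cell type labels (length = number of columns).
    pseudocount
        Added to every mean CPM before forming ratios; guarantees finite,
        non-negative values.
    exclude_labels
        Labels (e.g. an "unclassified" bin) removed from both the interest
        set and the reference set before anything is computed.
    """
    labels = np.asarray(class_labels)
    if labels.size != cpm_matrix.shape[1]:
        raise ValueError("one label per CPM column required")
    keep = ~np.isin(labels, list(exclude_labels))
    labels, cpm_matrix = labels[keep], cpm_matrix[:, keep]
    types = list(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("specificity needs at least two cell types")
    unknown = set(exclude_labels) - set(np.asarray(class_labels))
    if unknown:
        raise ValueError(f"exclude_labels not present in data: {sorted(unknown)}")

    n_per_type: dict[str, int] = {}
    means = np.empty((cpm_matrix.shape[0], len(types)))
    for j, t in enumerate(types):
        cols = labels == t
        n_per_type[t] = int(cols.sum())
        means[:, j] = cpm_matrix[:, cols].mean(axis=1)
    shifted = means + pseudocount

    spec = np.empty_like(means)
    for j in range(len(types)):
        others = np.delete(shifted, j, axis=1)
        spec[:, j] = (shifted[:, j][:, None] / others).min(axis=1)
    values = pd.DataFrame(spec, index=pd.Index(genes), columns=types)
    return SpecificityMatrix(values=values, n_per_type=n_per_type, pseudocount=pseudocount)


def top_specific_genes(spec: SpecificityMatrix, cell_type: str, n: int = 500) -> MarkerPanel:
    """The n genes with highest specificity for a cell type.

    Ties at the cutoff break lexicographically by gene id (smaller id
    kept), so the panel is deterministic.
    """
    if n <= 0:
        raise ValueError("panel size n must be positive")
    if cell_type not in spec.values.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    col = spec.values[cell_type]
    # sort by (-specificity, gene id): descending value, lexicographic ties
    order = sorted(col.index, key=lambda g: (-col[g], g))
    if n > len(order):
        logger.info(
            "top_specific_genes(%s): requested %d of %d genes; returning all",
            cell_type, n, len(order),
        )
    return MarkerPanel(cell_type=cell_type, genes=list(order[:n]), n_requested=n)
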