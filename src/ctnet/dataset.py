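"""Expression dataset container and on-disk layout.

The central object is :class:`ExpressionDataset`: a gene x nucleus count
matrix with per-nucleus annotations (cell class, optional cell cluster,
optional sequencing batch) and, once normalisation has run, a matching
``lognorm`` matrix of log2 library-size-normalised expression.

On disk a dataset is a directory in the conventional single-cell exchange
layout: ``matrix.mtx`` (genes x nuclei, Matrix Market), ``genes.tsv`` and
``barcodes.tsv`` (one identifier per line) and ``annotations.tsv`` with
columns ``nucleus_id, cell_class, cell_cluster, batch``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

ANNOT_COLUMNS = ["nucleus_id", "cell_class", "cell_cluster", "batch"]


@dataclass
class ExpressionDataset:
    """Gene x nucleus expression with per-nucleus annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_genes, n_nuclei)``.
    genes
        Unique ordered gene identifiers, length ``n_genes``.
    obs
        Per-nucleus annotation table indexed by unique nucleus id, rows
        aligned 1:1 with the columns of ``counts``. Must contain a
        ``cell_class`` column; ``cell_cluster`` and ``batch`` are optional.
    lognorm
        Log-normalised matrix of the same shape, or ``None`` before
        normalisation.
    """

    counts: np.ndarray
    genes: pd.Index
    obs: pd.DataFrame
    lognorm: np.ndarray | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.genes = pd.Index(self.genes)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional (genes x nuclei)")
        if self.counts.shape[0] != len(self.genes):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but {len(self.genes)} gene ids"
            )
        if self.counts.shape[1] != len(self.obs):
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but {len(self.obs)} annotation rows"
            )
        if self.genes.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.obs.index.has_duplicates:
            raise ValueError("duplicate nucleus identifiers")
        if "cell_class" not in self.obs.columns:
            raise ValueError("annotations must contain a 'cell_class' column")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.lognorm is not None and self.lognorm.shape != self.counts.shape:
            raise ValueError("lognorm shape must match counts shape")

    # -- basic properties -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    @property
    def nuclei(self) -> pd.Index:
        return self.obs.index

    @property
    def cell_classes(self) -> list[str]:
        """Distinct cell class labels, in order of first appearance."""
        return list(pd.unique(self.obs["cell_class"]))

    def class_columns(self, label_column: str = "cell_class") -> dict[str, np.ndarray]:
        """Column indices of each label value, preserving appearance order."""
        labels = self.obs[label_column].to_numpy()
        return {
            lab: np.flatnonzero(labels == lab) for lab in pd.unique(labels)
        }

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            counts=self.counts.copy(),
            genes=self.genes.copy(),
            obs=self.obs.copy(),
            lognorm=None if self.lognorm is None else self.lognorm.copy(),
            log=list(self.log),
        )

    def subset(
        self,
        gene_mask: np.ndarray | None = None,
        nucleus_mask: np.ndarray | None = None,
    ) -> "ExpressionDataset":
        """Subset along genes and/or nuclei by boolean or integer mask."""
        gi = np.arange(self.n_genes) if gene_mask is None else np.asarray(gene_mask)
        ni = np.arange(self.n_nuclei) if nucleus_mask is None else np.asarray(nucleus_mask)
        if gi.dtype == bool:
            gi = np.flatnonzero(gi)
        if ni.dtype == bool:
            ni = np.flatnonzero(ni)
        return ExpressionDataset(
            counts=self.counts[np.ix_(gi, ni)],
            genes=self.genes[gi],
            obs=self.obs.iloc[ni],
            lognorm=None if self.lognorm is None else self.lognorm[np.ix_(gi, ni)],
            log=list(self.log),
        )


def write_expression_dir(dataset: ExpressionDataset, directory: str | os.PathLike) -> dict[str, Path]:
    """Write a dataset as MTX + genes.tsv + barcodes.tsv + annotations.tsv.

    Returns a mapping of logical names to the written paths.
    """
    directory = Path(directory)
    if str(directory) == "":
        raise ValueError("empty directory path")
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create output directory {directory!s}: {exc}") from exc

    paths = {
        "matrix": directory / "matrix.mtx",
        "genes": directory / "genes.tsv",
        "barcodes": directory / "barcodes.tsv",
        "annotations": directory / "annotations.tsv",
    }
    try:
        spio.mmwrite(paths["matrix"], sparse.coo_matrix(dataset.counts.astype(np.int64)))
        paths["genes"].write_text("\n".join(dataset.genes) + "\n")
        paths["barcodes"].write_text("\n".join(dataset.nuclei) + "\n")
        annot = dataset.obs.copy()
        annot.insert(0, "nucleus_id", annot.index)
        for col in ANNOT_COLUMNS:
            if col not in annot.columns:
                annot[col] = ""
        annot[ANNOT_COLUMNS].to_csv(paths["annotations"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory!s}: {exc}") from exc
    return paths


def read_expression_dir(directory: str | os.PathLike) -> ExpressionDataset:
    """Read a dataset directory written by :func:`write_expression_dir`."""
    directory = Path(directory)
    matrix_path = directory / "matrix.mtx"
    if not matrix_path.exists():
        raise FileNotFoundError(f"no matrix.mtx in {directory!s}")
    counts = np.asarray(spio.mmread(matrix_path).todense()).astype(np.int64)
    genes = [ln.strip() for ln in (directory / "genes.tsv").read_text().splitlines() if ln.strip()]
    barcodes = [
        ln.strip() for ln in (directory / "barcodes.tsv").read_text().splitlines() if ln.strip()
    ]
    annot = pd.read_csv(directory / "annotations.tsv", sep="\t", dtype=str)
    annot = annot.set_index("nucleus_id").loc[barcodes]
    # batch labels round-trip as strings; empty optional columns become None
    for col in ("cell_cluster", "batch"):
        if col in annot.columns and (annot[col].isna().all() or (annot[col] == "").all()):
            annot = annot.drop(columns=[col])
    return ExpressionDataset(counts=counts, genes=pd.Index(genes), obs=annot)
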