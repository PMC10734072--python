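"""Core in-memory containers for expression matrices.

The canonical orientation everywhere in this package is genes as rows and
samples as columns, matching how bulk RNA-seq count matrices are written to
disk by most quantification pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass
class ExpressionDataset:
    """A genes x samples non-negative expression matrix with annotation.

    Parameters
    ----------
    values
        Non-negative matrix, shape ``(n_genes, n_samples)``. Integer-valued
        when ``data_kind == "counts"``.
    gene_ids, sample_ids
        Unique identifiers matching the matrix dimensions.
    chromosome
        Per-gene chromosome label ("1".."22", "X", "Y", "MT"); may be None
        for matrices that have already been filtered.
    data_kind
        ``"counts"`` for raw counts, ``"normalized"`` for pre-normalized
        log-intensity data (e.g. quantile-normalized microarray), which
        bypasses size-factor estimation and variance stabilization.
    truth
        Optional ground truth for synthetic data: ``{"labels": array of
        per-sample cluster indices, "signatures": {cluster: [gene ids]}}``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    chromosome: list[str] | None = None
    data_kind: str = "counts"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene IDs x {len(self.sample_ids)} sample IDs"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.data_kind not in ("counts", "normalized"):
            raise ValueError(f"unknown data_kind {self.data_kind!r}")
        if self.data_kind == "counts" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ValueError("counts mode requires integer values")
        if self.chromosome is not None:
            self.chromosome = list(self.chromosome)
            if len(self.chromosome) != len(self.gene_ids):
                raise ValueError("chromosome annotation length mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        """Restrict to the given genes, preserving the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing[:5]}...")
        rows = [index[g] for g in genes]
        return ExpressionDataset(
            values=self.values[rows],
            gene_ids=list(genes),
            sample_ids=self.sample_ids,
            chromosome=[self.chromosome[i] for i in rows] if self.chromosome else None,
            data_kind=self.data_kind,
            truth=self.truth,
        )


@dataclass
class NormalizedMatrix:
    """Variance-stabilized expression matrix with its normalization record."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    size_factors: np.ndarray
    genes_removed: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
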