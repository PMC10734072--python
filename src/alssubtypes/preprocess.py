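"""Count normalization, gene filtering, variance stabilization, and
variable-gene selection.

The stage mirrors the standard DESeq2-style preprocessing of bulk RNA-seq
before unsupervised clustering: median-of-ratios size factors, removal of
lowly expressed and non-autosomal genes, a variance-stabilizing transform,
and ranking genes by median absolute deviation (MAD) to keep the most
variable ones. Pre-normalized input (``data_kind == "normalized"``, e.g.
quantile-normalized log microarray intensities) passes through untouched.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np

from .data import AUTOSOMES, ExpressionDataset, NormalizedMatrix


def size_factors(counts: ExpressionDataset) -> np.ndarray:
    """Median-of-ratios size factors, geometric-mean normalized to 1.

    The per-gene reference is the geometric mean across samples, computed
    over genes with no zero count; each sample's factor is the median ratio
    of its counts to the reference over those genes, rescaled so the size
    factors have geometric mean 1.
    """
    if counts.data_kind != "counts":
        raise ValueError("size factors are defined for raw counts only")
    V = counts.values
    all_positive = np.all(V > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "median-of-ratios requires at least one gene with nonzero "
            "counts in every sample"
        )
    logref = np.mean(np.log(V[all_positive]), axis=1)
    logratios = np.log(V[all_positive]) - logref[:, None]
    sf = np.exp(np.median(logratios, axis=0))
    sf /= np.exp(np.mean(np.log(sf)))
    return sf


def filter_genes(data: ExpressionDataset, min_total_count: int = 10,
                 annotation: dict[str, str] | None = None,
                 missing_annotation: str = "error") -> ExpressionDataset:
    """Drop lowly expressed and non-autosomal genes.

    Genes survive iff their total count across samples is at least
    ``min_total_count`` and their chromosome is an autosome (1..22). The
    removal ledger is attached to the returned dataset as
    ``genes_removed``. Annotation comes from ``annotation`` (gene id ->
    chromosome) or, if None, from the dataset's own chromosome labels.
    ``missing_annotation`` is "error" or "drop".
    """
    if annotation is None:
        if data.chromosome is None:
            raise ValueError("no chromosome annotation available")
        annotation = dict(zip(data.gene_ids, data.chromosome))
    removed: dict[str, list[str]] = {"low_expression": [], "non_autosomal": [],
                                     "unannotated": []}
    totals = data.values.sum(axis=1)
    keep_rows = []
    for i, g in enumerate(data.gene_ids):
        chrom = annotation.get(g)
        if chrom is None:
            if missing_annotation == "error":
                raise KeyError(f"gene {g} has no chromosome annotation")
            removed["unannotated"].append(g)
            continue
        if chrom not in AUTOSOMES:
            removed["non_autosomal"].append(g)
            continue
        if totals[i] < min_total_count:
            removed["low_expression"].append(g)
            continue
        keep_rows.append(i)
    if not keep_rows:
        raise ValueError("filtering removed every gene")
    out = ExpressionDataset(
        values=data.values[keep_rows],
        gene_ids=[data.gene_ids[i] for i in keep_rows],
        sample_ids=data.sample_ids,
        chromosome=[annotation[data.gene_ids[i]] for i in keep_rows],
        data_kind=data.data_kind,
        truth=data.truth,
    )
    out.genes_removed = removed
    return out


def vst_transform(counts: ExpressionDataset, sf: np.ndarray,
                  transform: Callable[[np.ndarray], np.ndarray] | None = None,
                  ) -> NormalizedMatrix:
    """Variance-stabilizing transform of size-factor-normalized counts.

    Default transform is ``log2(count / sf + 1)``, a monotone stand-in for
    a parametric variance-stabilizing transform; an alternative transform
    of the normalized counts can be plugged in via ``transform``.
    """
    if np.any(counts.values < 0):
        raise ValueError("negative counts")
    sf = np.asarray(sf, dtype=float)
    if sf.shape != (counts.n_samples,) or np.any(sf <= 0):
        raise ValueError("size factors must be positive, one per sample")
    normalized = counts.values / sf[None, :]
    if transform is None:
        values = np.log2(normalized + 1.0)
    else:
        values = transform(normalized)
    removed = getattr(counts, "genes_removed", {})
    return NormalizedMatrix(values=values, gene_ids=list(counts.gene_ids),
                            sample_ids=list(counts.sample_ids),
                            size_factors=sf, genes_removed=removed)


def mad(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain median absolute deviation (no consistency constant)."""
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


def select_variable_genes(matrix: NormalizedMatrix, n_top: int = 5000) -> list[str]:
    """IDs of the ``n_top`` most variable genes by row MAD.

    Ties in MAD are broken by gene ID lexicographic order so selection is
    deterministic.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    n_genes = len(matrix.gene_ids)
    if n_top > n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds the {n_genes} available genes; "
            "returning all genes"
        )
        n_top = n_genes
    mads = mad(matrix.values, axis=1)
    order = sorted(range(n_genes), key=lambda i: (-mads[i], matrix.gene_ids[i]))
    return [matrix.gene_ids[i] for i in order[:n_top]]


def preprocess_counts(data: ExpressionDataset, min_total_count: int = 10,
                      n_top: int = 5000,
                      annotation: dict[str, str] | None = None,
                      ) -> tuple[NormalizedMatrix, list[str]]:
    """Full preprocessing: filter, normalize, transform, select.

    Pre-normalized data skips size factors and the transform. Returns the
    normalized matrix (all surviving genes) and the selected variable-gene
    IDs.
    """
    if data.data_kind == "normalized":
        norm = NormalizedMatrix(values=data.values, gene_ids=list(data.gene_ids),
                                sample_ids=list(data.sample_ids),
                                size_factors=np.ones(data.n_samples))
        return norm, select_variable_genes(norm, n_top)
    filtered = filter_genes(data, min_total_count=min_total_count,
                            annotation=annotation)
    sf = size_factors(filtered)
    norm = vst_transform(filtered, sf)
    return norm, select_variable_genes(norm, n_top)
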