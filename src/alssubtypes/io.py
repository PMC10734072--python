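"""On-disk formats: expression TSV/CSV/MTX, annotation, phenotypes, truth.

Genes-as-rows is the canonical orientation on disk; ``orientation=
"samples_by_genes"`` transposes on read. MatrixMarket files need two
sidecar files (``<stem>.genes.txt``, ``<stem>.samples.txt``) with one ID
per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .data import ExpressionDataset


def read_expression(path: str | Path, fmt: str | None = None,
                    orientation: str = "genes_by_samples",
                    data_kind: str = "counts",
                    annotation: dict[str, str] | None = None,
                    ) -> ExpressionDataset:
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name}")
    if fmt == "mtx":
        values, gene_ids, sample_ids = _read_mtx(path)
    else:
        sep = "\t" if fmt == "tsv" else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise ValueError(f"{path}: duplicate row or column IDs")
        values = frame.to_numpy(dtype=float)
        gene_ids = [str(g) for g in frame.index]
        sample_ids = [str(s) for s in frame.columns]
    if orientation == "samples_by_genes":
        values = values.T
        gene_ids, sample_ids = sample_ids, gene_ids
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value at gene row {bad[0] + 1}, "
            f"sample column {bad[1] + 1}"
        )
    chrom = ([annotation[g] for g in gene_ids] if annotation else None)
    return ExpressionDataset(values=values, gene_ids=gene_ids,
                             sample_ids=sample_ids, chromosome=chrom,
                             data_kind=data_kind)


def _read_mtx(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    genes_file = path.with_suffix("").with_suffix(".genes.txt")
    samples_file = path.with_suffix("").with_suffix(".samples.txt")
    for f in (genes_file, samples_file):
        if not f.exists():
            raise FileNotFoundError(f"MTX sidecar missing: {f}")
    gene_ids = genes_file.read_text().split()
    sample_ids = samples_file.read_text().split()
    try:
        mat = mmread(str(path))
    except Exception as exc:  # index errors surface with the entry
        raise ValueError(f"{path}: invalid MatrixMarket file ({exc})") from exc
    values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat,
                        dtype=float)
    if values.shape != (len(gene_ids), len(sample_ids)):
        raise ValueError(
            f"{path}: matrix is {values.shape} but sidecars list "
            f"{len(gene_ids)} genes x {len(sample_ids)} samples"
        )
    return values, gene_ids, sample_ids


def write_expression(ds: ExpressionDataset, path: str | Path,
                     fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "mtx":
        mmwrite(str(path), coo_matrix(ds.values))
        path.with_suffix("").with_suffix(".genes.txt").write_text(
            "\n".join(ds.gene_ids) + "\n")
        path.with_suffix("").with_suffix(".samples.txt").write_text(
            "\n".join(ds.sample_ids) + "\n")
    else:
        sep = "\t" if fmt == "tsv" else ","
        ds.to_frame().to_csv(path, sep=sep)


def write_annotation(ds: ExpressionDataset, path: str | Path) -> None:
    if ds.chromosome is None:
        raise ValueError("dataset has no chromosome annotation")
    pd.DataFrame({"gene_id": ds.gene_ids, "chromosome": ds.chromosome}
                 ).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "chromosome"} <= set(frame.columns):
        raise ValueError("annotation needs gene_id and chromosome columns")
    return dict(zip(frame["gene_id"], frame["chromosome"]))


def write_truth(ds: ExpressionDataset, path: str | Path) -> None:
    if ds.truth is None:
        raise ValueError("dataset has no planted truth")
    payload = {
        "labels": {s: int(l) for s, l in zip(ds.sample_ids,
                                             ds.truth["labels"])},
        "signatures": {str(k): list(v)
                       for k, v in ds.truth["signatures"].items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
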