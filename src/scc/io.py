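"""Readers and writers for dense delimited and Matrix Market expression files.

Dense layout: first row = cell names, first column = gene names, genes in
rows. Sparse layout: a CellRanger-style trio — ``<stem>.mtx`` with 1-based
triplets (rows = genes, columns = cells) plus one-label-per-line name files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import ExpressionMatrix

__all__ = ["read_matrix", "write_matrix"]

_DELIMS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"tsv", "csv", "mtx"}:
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"tsv", "csv", "mtx"}:
        return suffix
    if suffix in {"txt", "tab"}:
        return "tsv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def _companion_paths(path: Path, genes_file, cells_file) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    gene_candidates = (
        [Path(genes_file)]
        if genes_file
        else [stem.with_suffix(".genes.txt"), path.parent / "genes.tsv", path.parent / "genes.txt"]
    )
    cell_candidates = (
        [Path(cells_file)]
        if cells_file
        else [stem.with_suffix(".cells.txt"), path.parent / "barcodes.tsv", path.parent / "cells.txt"]
    )
    genes = next((p for p in gene_candidates if p.exists()), None)
    cells = next((p for p in cell_candidates if p.exists()), None)
    if genes is None or cells is None:
        raise FileNotFoundError(
            f"gene/cell name files for {path} not found (looked for "
            f"{[str(p) for p in gene_candidates + cell_candidates]})"
        )
    return genes, cells


def _read_names(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_matrix(
    path,
    format: str | None = None,
    genes_file=None,
    cells_file=None,
    check_counts: bool = True,
) -> ExpressionMatrix:
    """Read an expression matrix, validating labels and nonnegativity.

    Parameters
    ----------
    path : path-like
        Dense TSV/CSV (header row of cell names, first column of gene
        names) or a Matrix Market ``.mtx`` file with companion name files.
    format : {"tsv", "csv", "mtx"}, optional
        Inferred from the extension when omitted.
    genes_file, cells_file : path-like, optional
        Explicit companion name files for ``mtx`` input.
    check_counts : bool
        Warn when the values do not look count-like.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input matrix not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        genes_path, cells_path = _companion_paths(path, genes_file, cells_file)
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        m = ExpressionMatrix(values, _read_names(genes_path), _read_names(cells_path))
    else:
        df = pd.read_csv(path, sep=_DELIMS[fmt], index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
        m = ExpressionMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])
    if check_counts:
        m.check_count_like()
    return m


def write_matrix(m: ExpressionMatrix, path, format: str | None = None) -> Path:
    """Write ``m`` to ``path``; round-trips values to 1e-9 relative tolerance.

    For ``mtx``, writes ``<stem>.genes.txt`` and ``<stem>.cells.txt``
    alongside the triplet file.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        sparse = scipy.sparse.coo_matrix(m.values)
        scipy.io.mmwrite(str(path), sparse, precision=12)
        stem = path.with_suffix("")
        stem.with_suffix(".genes.txt").write_text("\n".join(m.gene_names) + "\n", encoding="utf-8")
        stem.with_suffix(".cells.txt").write_text("\n".join(m.cell_names) + "\n", encoding="utf-8")
    else:
        m.to_dataframe().to_csv(path, sep=_DELIMS[fmt], float_format="%.12g")
    return path
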