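"""Reading, writing and preprocessing expression-style matrices.

Supported formats: delimited text (CSV/TSV, header row of feature names,
optional first column of observation names) and MatrixMarket coordinate
triplets with plain-text row/column name sidecars (``<stem>_rows.txt`` and
``<stem>_cols.txt`` next to the ``.mtx`` file).  Matrices are returned dense
with observations in rows; an ``orientation`` flag transposes matrices stored
genes-by-cells.

``preprocess`` implements the standard single-cell conventions: QC filtering
(minimum expressed genes per cell, minimum total counts, maximum
mitochondrial fraction by gene-name prefix), per-cell total-count
normalization to a target scale (default: the median cell total), a
``log2(x + 1)`` transform, and selection of the top-variance features.  All
steps default to off.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = ["MatrixData", "read_matrix", "write_matrix", "preprocess"]


class MatrixParseError(ValueError):
    pass


@dataclass
class MatrixData:
    """A dense numeric matrix with optional row/column names (rows = observations)."""

    values: np.ndarray
    row_names: list[str] | None = None
    col_names: list[str] | None = None

    @property
    def shape(self):
        return self.values.shape


def _sidecar_names(path: Path) -> tuple[list[str] | None, list[str] | None]:
    rows = path.with_name(path.stem + "_rows.txt")
    cols = path.with_name(path.stem + "_cols.txt")
    rn = rows.read_text().splitlines() if rows.exists() else None
    cn = cols.read_text().splitlines() if cols.exists() else None
    return rn, cn


def read_matrix(
    path, fmt: str | None = None, observations_in_rows: bool = True
) -> MatrixData:
    """Read a matrix from CSV, TSV or MatrixMarket triplet format.

    ``fmt`` is inferred from the extension when omitted.  Set
    ``observations_in_rows=False`` for matrices stored features-by-
    observations (they are transposed on read).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(path.suffix.lower())
        if fmt is None:
            raise MatrixParseError(f"cannot infer format from suffix {path.suffix!r}")

    if fmt == "mtx":
        try:
            values = np.asarray(mmread(path).todense(), dtype=float)
        except Exception as exc:  # scipy raises bare ValueError on bad files
            raise MatrixParseError(f"{path}: invalid MatrixMarket file: {exc}") from exc
        rn, cn = _sidecar_names(path)
        if rn is not None and len(rn) != values.shape[0]:
            raise MatrixParseError(
                f"{path}: row sidecar has {len(rn)} names for {values.shape[0]} rows"
            )
        if cn is not None and len(cn) != values.shape[1]:
            raise MatrixParseError(
                f"{path}: column sidecar has {len(cn)} names for {values.shape[1]} columns"
            )
        data = MatrixData(values=values, row_names=rn, col_names=cn)
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            frame = pd.read_csv(path, sep=sep)
        except pd.errors.EmptyDataError as exc:
            raise MatrixParseError(f"{path}: empty file") from exc
        except pd.errors.ParserError as exc:
            raise MatrixParseError(f"{path}: {exc}") from exc
        row_names = None
        first = frame.columns[0]
        if len(frame.columns) > 1 and frame[first].dtype == object:
            row_names = frame[first].astype(str).tolist()
            frame = frame.drop(columns=[first])
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().to_numpy().any() and not frame.isna().to_numpy().any():
            bad = np.argwhere(numeric.isna().to_numpy())[0]
            raise MatrixParseError(
                f"{path}: non-numeric cell at data line {bad[0] + 2}, column "
                f"{frame.columns[bad[1]]!r}"
            )
        if numeric.isna().to_numpy().any():
            bad = np.argwhere(numeric.isna().to_numpy())[0]
            raise MatrixParseError(f"{path}: missing value at data line {bad[0] + 2}")
        data = MatrixData(
            values=numeric.to_numpy(dtype=float),
            row_names=row_names,
            col_names=[str(c) for c in frame.columns],
        )
    else:
        raise MatrixParseError(f"unknown format {fmt!r}")

    if not observations_in_rows:
        data = MatrixData(
            values=data.values.T, row_names=data.col_names, col_names=data.row_names
        )
    return data


def write_matrix(data: MatrixData, path, fmt: str | None = None) -> None:
    """Write a matrix in CSV/TSV (full float precision) or MatrixMarket format."""
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(path.suffix.lower())
    if fmt == "mtx":
        mmwrite(path, coo_matrix(data.values), precision=17)
        if data.row_names is not None:
            path.with_name(path.stem + "_rows.txt").write_text("\n".join(data.row_names) + "\n")
        if data.col_names is not None:
            path.with_name(path.stem + "_cols.txt").write_text("\n".join(data.col_names) + "\n")
        return
    sep = "," if fmt == "csv" else "\t"
    cols = data.col_names or [f"V{i+1}" for i in range(data.values.shape[1])]
    frame = pd.DataFrame(data.values, columns=cols)
    if data.row_names is not None:
        frame.insert(0, "row", data.row_names)
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


def preprocess(
    x: np.ndarray,
    gene_names: list[str] | None = None,
    min_genes_per_cell: int | None = None,
    min_counts_per_cell: float | None = None,
    max_mito_frac: float | None = None,
    mito_prefix: str = "MT-",
    normalize: bool = False,
    target_scale: float | None = None,
    log2_transform: bool = False,
    top_var: int | None = None,
):
    """Count-matrix QC, normalization, log transform, variance selection.

    With all options off this is the identity.  Returns
    ``(matrix, kept_rows, kept_cols)`` with the index arrays referring to the
    input.  Normalization maps a cell with total ``c`` and entry ``g`` to
    ``g * s / c`` for target scale ``s`` (median cell total by default);
    the log transform is ``log2(x + 1)``; ``top_var`` keeps the ``top_var``
    columns with the largest sample variance (ties broken by column order).
    """
    x = np.asarray(x, dtype=float)
    n, q = x.shape
    kept_rows = np.arange(n)

    keep = np.ones(n, dtype=bool)
    if min_genes_per_cell is not None:
        keep &= (x > 0).sum(axis=1) >= min_genes_per_cell
    if min_counts_per_cell is not None:
        keep &= x.sum(axis=1) >= min_counts_per_cell
    if max_mito_frac is not None:
        if gene_names is None:
            raise ValueError("mitochondrial filtering needs gene names")
        mito = np.array([g.startswith(mito_prefix) for g in gene_names])
        totals = x.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, x[:, mito].sum(axis=1) / totals, 0.0)
        keep &= frac <= max_mito_frac
    if not np.any(keep):
        raise ValueError("preprocessing filtered out every cell")
    x = x[keep]
    kept_rows = kept_rows[keep]

    if normalize:
        totals = x.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("cannot normalize cells with non-positive totals")
        s = float(np.median(totals)) if target_scale is None else float(target_scale)
        x = x * (s / totals)[:, None]
    if log2_transform:
        x = np.log2(x + 1.0)

    kept_cols = np.arange(q)
    if top_var is not None:
        if top_var > x.shape[1]:
            raise ValueError("top_var exceeds the number of features")
        var = x.var(axis=0, ddof=1)
        # stable sort descending: ties keep original column order
        order = np.argsort(-var, kind="stable")[:top_var]
        kept_cols = np.sort(order)
        x = x[:, kept_cols]
    return x, kept_rows, kept_cols
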