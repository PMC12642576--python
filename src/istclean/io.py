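"""Readers and writers for the on-disk formats.

Counts travel as Matrix Market coordinate files with sibling one-column
TSVs for gene and cell identifiers (order defines matrix orientation);
cell geometry as a TSV with header ``cell_id  x  y`` (μm); transcript
molecules as CSV with configurable column names defaulting to the Xenium
``transcripts.csv`` dialect (``x_location, y_location, feature_name``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from ._errors import ValidationError
from .mixture import DenoiseResult
from .spatial import validate_cell_table

XENIUM_TX_COLUMNS = {"x": "x_location", "y": "y_location", "gene": "feature_name"}


def _read_id_column(path: str | Path) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate identifiers in {path}")
    return ids


def read_count_matrix(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    genes_as_rows: bool = False,
    allow_real: bool = False,
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Read counts plus identifiers; returns (cells × genes CSR, cell_ids, genes).

    On-disk orientation is declared with ``genes_as_rows``; the in-memory
    result is always cells × genes.  Non-integer values are rejected unless
    ``allow_real`` (metrics on fractional counts).
    """
    M = scipy_io.mmread(str(mtx_path)).tocsr()
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    if genes_as_rows:
        M = M.T.tocsr()
    if M.shape != (len(cells), len(genes)):
        raise ValidationError(
            f"matrix {mtx_path} has shape {M.shape} but {cells_path} lists "
            f"{len(cells)} cells and {genes_path} lists {len(genes)} genes "
            f"(genes_as_rows={genes_as_rows})"
        )
    if not allow_real:
        data = M.data
        if not np.allclose(data, np.round(data)):
            raise ValidationError(
                f"{mtx_path} contains non-integer values; pass allow_real=True "
                "only for metric computations on fractional counts"
            )
        M = M.astype(np.int64)
    if M.nnz and M.data.min() < 0:
        raise ValidationError(f"{mtx_path} contains negative values")
    return M, cells, genes


def write_count_matrix(
    out_dir: str | Path,
    matrix,
    cell_ids: list[str],
    gene_names: list[str],
    prefix: str = "counts",
) -> dict[str, Path]:
    """Write ``<prefix>.mtx`` with sibling ``genes.tsv`` / ``cells.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    M = sparse.coo_matrix(matrix)
    if M.shape != (len(cell_ids), len(gene_names)):
        raise ValidationError(
            f"matrix shape {M.shape} does not match {len(cell_ids)} cells × "
            f"{len(gene_names)} genes"
        )
    paths = {
        "mtx": out / f"{prefix}.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    scipy_io.mmwrite(str(paths["mtx"]), M)
    pd.Series(gene_names).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(cell_ids).to_csv(paths["cells"], sep="\t", index=False, header=False)
    return paths


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with header ``cell_id  x  y`` (coordinates in μm)."""
    df = pd.read_csv(path, sep="\t")
    validate_cell_table(df)
    df["cell_id"] = df["cell_id"].astype(str)
    return df[["cell_id", "x", "y"] + [c for c in df.columns if c not in ("cell_id", "x", "y")]]


def read_transcripts(
    path: str | Path,
    x_col: str = XENIUM_TX_COLUMNS["x"],
    y_col: str = XENIUM_TX_COLUMNS["y"],
    gene_col: str = XENIUM_TX_COLUMNS["gene"],
    min_quality: float | None = None,
    quality_col: str = "qv",
) -> pd.DataFrame:
    """Read a transcript CSV/TSV (gz accepted) into columns ``x, y, gene``.

    No quality filtering is applied by default; pass ``min_quality`` to drop
    rows whose ``quality_col`` falls below it.
    """
    sep = "\t" if str(path).rstrip(".gz").endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in (x_col, y_col, gene_col):
        if col not in df.columns:
            raise ValidationError(
                f"transcript file {path} lacks column {col!r}; "
                f"available: {list(df.columns)}"
            )
    if min_quality is not None:
        if quality_col not in df.columns:
            raise ValidationError(f"quality column {quality_col!r} not in {path}")
        df = df[df[quality_col] >= min_quality]
    out = df[[x_col, y_col, gene_col]].rename(
        columns={x_col: "x", y_col: "y", gene_col: "gene"}
    )
    out["gene"] = out["gene"].astype(str)
    return out.reset_index(drop=True)


def write_denoise_result(
    out_dir: str | Path,
    result: DenoiseResult,
    write_posterior: bool = False,
) -> dict[str, Path]:
    """Write adjusted counts, the per-cell fit table and the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_count_matrix(
        out, result.adjusted, result.cell_ids, result.gene_names, prefix="adjusted"
    )
    fits_path = out / "fits.tsv"
    result.fits.to_csv(fits_path, sep="\t", index=False)
    paths["fits"] = fits_path
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
        fh.write("\n")
    paths["report"] = report_path
    if write_posterior:
        post = np.nan_to_num(result.posterior, nan=0.0)
        pth = out / "posterior.mtx"
        scipy_io.mmwrite(str(pth), sparse.coo_matrix(post))
        paths["posterior"] = pth
    return paths


def write_simulation(out_dir: str | Path, ds) -> dict[str, Path]:
    """Write a synthetic dataset: counts, tables, transcripts and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_count_matrix(out, ds.counts, ds.cells["cell_id"].tolist(), ds.gene_names)
    cells_path = out / "cells.tsv"
    ds.cells.to_csv(cells_path, sep="\t", index=False)
    tx_path = out / "transcripts.csv"
    ds.transcripts.rename(
        columns={"x": "x_location", "y": "y_location", "gene": "feature_name"}
    ).to_csv(tx_path, index=False)
    labels_path = out / "labels.tsv"
    pd.DataFrame(
        {"cell_id": ds.cells["cell_id"], "cell_type": ds.type_labels}
    ).to_csv(labels_path, sep="\t", index=False)
    truth_path = out / "truth.tsv"
    endo = ds.endogenous.tocoo()
    cont = ds.contaminated.tocoo()
    truth = pd.concat(
        [
            pd.DataFrame(
                {"cell": endo.row, "gene": endo.col, "count": endo.data,
                 "source": "endogenous"}
            ),
            pd.DataFrame(
                {"cell": cont.row, "gene": cont.col, "count": cont.data,
                 "source": "contaminated"}
            ),
        ]
    ).sort_values(["cell", "gene", "source"])
    truth.to_csv(truth_path, sep="\t", index=False)
    paths.update(cells=cells_path, transcripts=tx_path, labels=labels_path, truth=truth_path)
    return paths
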