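"""Readers and writers for the on-disk formats the pipeline consumes.

Single-cell expression comes as a 10x-style MatrixMarket triplet
(``matrix.mtx`` genes x cells + ``features.tsv`` + ``barcodes.tsv``, with an
optional ``layout.json`` sidecar recording the orientation) or a dense TSV;
per-cell metadata joins strictly by barcode from ``cells.tsv``.  Bulk counts
are a gene x sample TSV (samples as columns); phenotypes a sample x trait
TSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .errors import FormatError


def read_expression(path: str | Path) -> ad.AnnData:
    """Read single-cell expression into an AnnData (cells x genes).

    ``path`` is either a directory holding an MTX triplet or a dense TSV
    (genes as rows, cells as columns).  Duplicate gene names are
    disambiguated with numeric suffixes and logged via warning.
    """
    path = Path(path)
    if path.is_dir():
        adata = _read_mtx_dir(path)
    else:
        dense = pd.read_csv(path, sep="\t", index_col=0)
        adata = ad.AnnData(
            X=dense.to_numpy(dtype=float).T,
            obs=pd.DataFrame(index=dense.columns),
            var=pd.DataFrame(index=dense.index),
        )
    if adata.var_names.duplicated().any():
        warnings.warn("duplicate gene names disambiguated with suffixes", stacklevel=2)
        adata.var_names_make_unique()
    return adata


def _read_mtx_dir(path: Path) -> ad.AnnData:
    from scipy import io as spio

    mtx_path = path / "matrix.mtx"
    if not mtx_path.exists():
        raise FormatError(f"{mtx_path} not found")
    matrix = spio.mmread(str(mtx_path)).toarray()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    orientation = "genes_x_cells"
    layout = path / "layout.json"
    if layout.exists():
        orientation = json.loads(layout.read_text()).get("matrix_orientation", orientation)
    if orientation == "genes_x_cells":
        matrix = matrix.T  # -> cells x genes
    n_cells, n_genes = matrix.shape
    if n_genes != len(features):
        raise FormatError(
            f"features.tsv lists {len(features)} genes but matrix.mtx has {n_genes}"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"barcodes.tsv lists {len(barcodes)} cells but matrix.mtx has {n_cells}"
        )
    adata = ad.AnnData(
        X=matrix,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )
    meta_path = path / "cells.tsv"
    if meta_path.exists():
        adata = join_cell_metadata(adata, pd.read_csv(meta_path, sep="\t", index_col=0))
    return adata


def join_cell_metadata(adata: ad.AnnData, meta: pd.DataFrame) -> ad.AnnData:
    """Strict join of per-cell metadata by barcode (missing barcodes error)."""
    meta.index = meta.index.astype(str)
    missing = [b for b in adata.obs_names if b not in meta.index]
    if missing:
        shown = ", ".join(missing[:5])
        raise FormatError(
            f"{len(missing)} barcode(s) missing from metadata (e.g. {shown})"
        )
    adata.obs = meta.loc[adata.obs_names].copy()
    return adata


def read_bulk_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV into a sample x gene frame."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.T


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line (first column of a TSV also accepted)."""
    lines = Path(path).read_text().strip().splitlines()
    return [ln.split("\t")[0].strip() for ln in lines if ln.strip()]
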