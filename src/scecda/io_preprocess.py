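"""Reading omics matrices and the standard preprocessing recipe.

Preprocessing follows the usual single-cell workflow: drop features seen in
fewer than ``min_cells`` cells, depth-normalize each cell to the median depth,
log1p-transform, keep the top highly variable features (dispersion-based,
Seurat flavor), and standardize each feature to zero mean / unit variance with
outlier clipping. ADT (surface protein) panels are small and curated, so HVG
selection is skipped for them.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.io import mmread

from .types import LabelVector, OmicsMatrix

DEFAULT_N_HVG = {"RNA": 4000, "ATAC": 2000, "ADT": None}


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def load_matrix(
    path,
    format: str,
    modality: str,
    orientation: str | None = None,
    layer: str | None = None,
) -> OmicsMatrix:
    """Load one omics layer as a cells × features matrix.

    Parameters
    ----------
    format
        ``mtx_dir`` (10x-style directory with matrix.mtx + features.tsv +
        barcodes.tsv, gzip tolerated), ``csv`` (header row of feature names,
        optional leading cell-id column) or ``h5`` (one HDF5 group per layer
        with datasets ``X``, ``features``, ``barcodes``).
    orientation
        ``"cells_rows"`` or ``"features_rows"``; by default inferred by
        matching the barcode/feature counts against the matrix shape. An
        explicit value overrides auto-detection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        mat = sp.csr_matrix(mmread(_find(path, "matrix.mtx")))
        features = _read_lines(_find(path, "features.tsv"))
        barcodes = _read_lines(_find(path, "barcodes.tsv"))
        if orientation is None:
            if mat.shape == (len(barcodes), len(features)):
                orientation = "cells_rows"
            elif mat.shape == (len(features), len(barcodes)):
                orientation = "features_rows"
            else:
                raise ValueError(
                    f"matrix shape {mat.shape} matches neither "
                    f"{len(barcodes)} barcodes x {len(features)} features "
                    "nor its transpose"
                )
        if orientation == "features_rows":
            mat = sp.csr_matrix(mat.T)
        if mat.shape != (len(barcodes), len(features)):
            raise ValueError("dimension mismatch between matrix and name lists")
        return OmicsMatrix(mat, modality, features, barcodes, layer_name=path.name)
    if format == "csv":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep)
        if df.shape[1] and df.iloc[:, 0].dtype == object:
            df = df.set_index(df.columns[0])
        cells = [str(c) for c in df.index]
        feats = [str(c) for c in df.columns]
        mat = df.to_numpy(dtype=np.float64)
        if orientation == "features_rows":
            mat, cells, feats = mat.T, feats, cells
        return OmicsMatrix(mat, modality, feats, cells, layer_name=path.name)
    if format == "h5":
        with h5py.File(path, "r") as fh:
            grp = fh[layer or modality]
            mat = np.asarray(grp["X"], dtype=np.float64)
            feats = [s.decode() if isinstance(s, bytes) else str(s) for s in grp["features"][()]]
            cells = [s.decode() if isinstance(s, bytes) else str(s) for s in grp["barcodes"][()]]
        if orientation == "features_rows":
            mat = mat.T
        if mat.shape != (len(cells), len(feats)):
            raise ValueError("dimension mismatch between matrix and name lists")
        return OmicsMatrix(mat, modality, feats, cells, layer_name=layer or modality)
    raise ValueError(f"unknown format {format!r}")


def save_mtx_dir(X: OmicsMatrix, dirpath) -> None:
    """Write a layer as matrix.mtx (features × cells, 10x orientation) + lists."""
    from scipy.io import mmwrite

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    mmwrite(str(dirpath / "matrix.mtx"), sp.coo_matrix(X.values.T))
    (dirpath / "features.tsv").write_text("\n".join(X.feature_names) + "\n")
    (dirpath / "barcodes.tsv").write_text("\n".join(X.cell_ids) + "\n")


def load_labels(path) -> LabelVector:
    """Read a one-label-per-cell file (single column, optional header)."""
    path = Path(path)
    df = pd.read_csv(path, header=None)
    col = df.iloc[:, -1]
    # tolerate a header line on string columns
    if col.dtype == object and str(col.iloc[0]).lower() in {"label", "truth", "cell_type"}:
        col = col.iloc[1:]
    return LabelVector.from_values(col.to_numpy())


def preprocess(
    X: OmicsMatrix,
    n_hvg: int | None = None,
    min_cells: int = 2,
    clip_value: float = 10.0,
    hvg_flavor: str = "seurat",
    drop_zero_variance: bool = True,
) -> OmicsMatrix:
    """Filter, normalize, select variable features and standardize one layer.

    ``n_hvg`` defaults to 4000 for RNA, 2000 for ATAC and is skipped for ADT.
    Standardized values are clipped at ``±clip_value`` so extreme cells do not
    dominate the reconstruction objective.
    """
    if n_hvg is None:
        n_hvg = DEFAULT_N_HVG[X.modality]
    values = X.values if sp.issparse(X.values) else np.asarray(X.values, float)
    adata = ad.AnnData(
        sp.csr_matrix(values, dtype=np.float64)
        if not sp.issparse(values)
        else values.astype(np.float64).tocsr()
    )
    adata.obs_names = X.cell_ids
    adata.var_names = X.feature_names

    depths = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(depths == 0):
        warnings.warn(f"{int((depths == 0).sum())} all-zero cells retained")
    sc.pp.filter_genes(adata, min_cells=min_cells)
    if adata.n_vars == 0:
        raise ValueError("no features left after min_cells filtering")

    nonzero = depths[depths > 0]
    target = float(np.median(nonzero)) if nonzero.size else 1.0
    sc.pp.normalize_total(adata, target_sum=target)
    sc.pp.log1p(adata)

    if n_hvg is not None and X.modality != "ADT":
        if n_hvg > adata.n_vars:
            warnings.warn(
                f"n_hvg={n_hvg} exceeds {adata.n_vars} remaining features; clipped"
            )
            n_hvg = adata.n_vars
        if n_hvg < adata.n_vars:
            sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor=hvg_flavor)
            adata = adata[:, adata.var["highly_variable"]].copy()

    dense = np.asarray(adata.X.todense()) if sp.issparse(adata.X) else np.asarray(adata.X)
    dense = dense.astype(np.float64)
    if drop_zero_variance:
        keep = dense.std(axis=0) > 0
        if not keep.all():
            adata = adata[:, keep].copy()
            dense = dense[:, keep]
    # standardize to zero mean / unit (population) variance, clip outliers
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0  # variance guard: constant features become zeros
    out = np.clip((dense - mu) / sd, -clip_value, clip_value)
    return OmicsMatrix(
        out,
        X.modality,
        [str(v) for v in adata.var_names],
        list(X.cell_ids),
        layer_name=X.layer_name,
    )
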