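"""Readers and writers for ModalityBundle containers.

Three on-disk formats are supported:

``mtx_dir``
    A directory of MatrixMarket files, one per layer (``spliced.mtx``,
    ``unspliced.mtx``, optionally ``velocity.mtx`` ...), stored genes x
    cells (cells in columns, the common velocity-tool convention) with
    1-based MatrixMarket indexing, plus ``genes.tsv`` / ``cells.tsv``
    metadata sidecars.  An optional ``<layer>_genes.tsv`` sidecar declares a
    layer-specific gene order; the layer is realigned by gene_id on load.
``loom``
    An HDF5 file with the loom layout (``/matrix`` holding spliced counts
    genes x cells, extra layers under ``/layers``, ``Gene`` / ``CellID``
    attribute vectors).  An optional ``Gene_<layer>`` row attribute declares
    a layer-specific gene order, realigned on load.
``h5ad``
    The AnnData HDF5 container (X = spliced, remaining layers in
    ``.layers``), via :mod:`anndata`.

Layer alignment is always verified by name matching, never by assuming
identical storage order.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .bundle import AlignmentError, BundleError, ModalityBundle

FORMATS = ("mtx_dir", "loom", "h5ad")


class FormatError(BundleError):
    """A file does not match the expected on-disk layout."""


def _realign_layer(mat: np.ndarray, layer_genes, master_genes, layer: str) -> np.ndarray:
    """Reorder the columns of ``mat`` from ``layer_genes`` to ``master_genes``."""
    layer_genes = list(map(str, layer_genes))
    master_genes = list(map(str, master_genes))
    if layer_genes == master_genes:
        return mat
    pos = {g: i for i, g in enumerate(layer_genes)}
    try:
        order = [pos[g] for g in master_genes]
    except KeyError as exc:
        raise AlignmentError(
            f"layer {layer!r} gene order cannot be aligned: gene {exc} missing"
        ) from exc
    if len(pos) != len(master_genes):
        raise AlignmentError(
            f"layer {layer!r} has {len(pos)} genes, master table has {len(master_genes)}"
        )
    return mat[:, order]


# ---------------------------------------------------------------------------
# mtx_dir
# ---------------------------------------------------------------------------

def _load_mtx_dir(path: Path) -> ModalityBundle:
    for req in ("spliced.mtx", "unspliced.mtx", "genes.tsv", "cells.tsv"):
        if not (path / req).exists():
            raise FormatError(f"mtx_dir {path} is missing {req}")
    gene_meta = pd.read_csv(path / "genes.tsv", sep="\t", index_col=0)
    cell_meta = pd.read_csv(path / "cells.tsv", sep="\t", index_col=0)
    gene_meta.index = gene_meta.index.astype(str)
    cell_meta.index = cell_meta.index.astype(str)
    layers: Dict[str, np.ndarray] = {}
    for f in sorted(path.glob("*.mtx")):
        layer = f.stem
        mat = np.asarray(scipy.io.mmread(f).todense(), dtype=float).T  # -> cells x genes
        side = path / f"{layer}_genes.tsv"
        if side.exists():
            layer_genes = pd.read_csv(side, sep="\t", index_col=0).index.astype(str)
            mat = _realign_layer(mat, layer_genes, gene_meta.index, layer)
        if mat.shape != (len(cell_meta), len(gene_meta)):
            raise AlignmentError(
                f"layer {layer!r} has shape {mat.shape}, metadata implies "
                f"{(len(cell_meta), len(gene_meta))}"
            )
        layers[layer] = mat
    return ModalityBundle(layers=layers, cell_meta=cell_meta, gene_meta=gene_meta)


def _save_mtx_dir(bundle: ModalityBundle, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for layer, mat in bundle.layers.items():
        scipy.io.mmwrite(str(path / f"{layer}.mtx"), sp.coo_matrix(mat.T))
    bundle.gene_meta.to_csv(path / "genes.tsv", sep="\t", index_label="gene_id")
    bundle.cell_meta.to_csv(path / "cells.tsv", sep="\t", index_label="cell_id")


# ---------------------------------------------------------------------------
# loom (minimal HDF5 layout)
# ---------------------------------------------------------------------------

def _decode(arr) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype.kind in ("S", "O"):
        return np.array([x.decode() if isinstance(x, bytes) else str(x) for x in arr])
    return arr


def _load_loom(path: Path) -> ModalityBundle:
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError(f"{path} has no /matrix dataset (not a loom file)")
        genes = _decode(f["row_attrs/Gene"][:])
        cells = _decode(f["col_attrs/CellID"][:])
        layers = {"spliced": np.asarray(f["matrix"][:], dtype=float).T}
        if "layers" in f:
            for layer in f["layers"]:
                mat = np.asarray(f["layers"][layer][:], dtype=float).T
                key = f"Gene_{layer}"
                if key in f["row_attrs"]:
                    mat = _realign_layer(mat, _decode(f["row_attrs"][key][:]), genes, layer)
                layers[layer] = mat
        cell_meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
        for col in f["col_attrs"]:
            if col != "CellID":
                cell_meta[col] = _decode(f["col_attrs"][col][:])
        gene_meta = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
        for col in f["row_attrs"]:
            if col != "Gene" and not col.startswith("Gene_"):
                gene_meta[col] = _decode(f["row_attrs"][col][:])
    if "unspliced" not in layers:
        raise FormatError(f"{path} lacks an 'unspliced' layer")
    return ModalityBundle(layers=layers, cell_meta=cell_meta, gene_meta=gene_meta)


def _str_array(values) -> np.ndarray:
    return np.array([str(v) for v in values], dtype=h5py.string_dtype())


def _save_loom(bundle: ModalityBundle, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=bundle.layers["spliced"].T)
        grp = f.create_group("layers")
        for layer, mat in bundle.layers.items():
            if layer != "spliced":
                grp.create_dataset(layer, data=mat.T)
        row = f.create_group("row_attrs")
        row.create_dataset("Gene", data=_str_array(bundle.gene_ids))
        for col in bundle.gene_meta.columns:
            vals = bundle.gene_meta[col].to_numpy()
            if vals.dtype.kind in ("O", "U", "b"):
                row.create_dataset(col, data=_str_array(vals))
            else:
                row.create_dataset(col, data=vals)
        colg = f.create_group("col_attrs")
        colg.create_dataset("CellID", data=_str_array(bundle.cell_ids))
        for col in bundle.cell_meta.columns:
            vals = bundle.cell_meta[col].to_numpy()
            if vals.dtype.kind in ("O", "U", "b"):
                colg.create_dataset(col, data=_str_array(vals))
            else:
                colg.create_dataset(col, data=vals)


# ---------------------------------------------------------------------------
# h5ad
# ---------------------------------------------------------------------------

def _load_h5ad(path: Path) -> ModalityBundle:
    import anndata

    adata = anndata.read_h5ad(path)
    layers = {"spliced": np.asarray(adata.X if not sp.issparse(adata.X) else adata.X.todense(), dtype=float)}
    for layer in adata.layers:
        mat = adata.layers[layer]
        layers[layer] = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
    if "unspliced" not in layers:
        raise FormatError(f"{path} lacks an 'unspliced' layer")
    cell_meta = adata.obs.copy()
    cell_meta.index = cell_meta.index.astype(str).rename("cell_id")
    gene_meta = adata.var.copy()
    gene_meta.index = gene_meta.index.astype(str).rename("gene_id")
    return ModalityBundle(layers=layers, cell_meta=cell_meta, gene_meta=gene_meta)


def _save_h5ad(bundle: ModalityBundle, path: Path) -> None:
    import anndata

    extra = {k: v for k, v in bundle.layers.items() if k != "spliced"}
    obs = bundle.cell_meta.copy()
    obs.index = obs.index.astype(str)
    var = bundle.gene_meta.copy()
    var.index = var.index.astype(str)
    adata = anndata.AnnData(X=bundle.layers["spliced"].copy(), obs=obs, var=var, layers=extra)
    adata.write_h5ad(path)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def load_bundle(path, format: str = "mtx_dir") -> ModalityBundle:
    """Load a ModalityBundle from disk.

    Raises :class:`FormatError` when required layers or sidecars are
    missing, and :class:`AlignmentError` when layers disagree on dimensions
    or gene identity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        return _load_mtx_dir(path)
    if format == "loom":
        return _load_loom(path)
    if format == "h5ad":
        return _load_h5ad(path)
    raise ValueError(f"unknown format {format!r}; supported: {FORMATS}")


def save_bundle(bundle: ModalityBundle, path, format: str = "mtx_dir") -> None:
    """Write a ModalityBundle; inverse of :func:`load_bundle` up to storage order."""
    if bundle.n_cells == 0 or bundle.n_genes == 0:
        raise BundleError("refusing to write a degenerate bundle with 0 cells or genes")
    path = Path(path)
    if path.parent and not path.parent.exists():
        os.makedirs(path.parent, exist_ok=True)
    if format == "mtx_dir":
        _save_mtx_dir(bundle, path)
    elif format == "loom":
        _save_loom(bundle, path)
    elif format == "h5ad":
        _save_h5ad(bundle, path)
    else:
        raise ValueError(f"unknown format {format!r}; supported: {FORMATS}")
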