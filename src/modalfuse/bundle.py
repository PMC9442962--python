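"""Core containers for paired-modality single-cell data.

The central object is :class:`ModalityBundle`, which holds several cells x
genes layers over the *same* cells and genes -- at minimum spliced (mature
mRNA) and unspliced (pre-mRNA) molecule counts, optionally their k-NN
moments and an RNA-velocity layer.  All downstream stages (preprocessing,
batch correction, velocity estimation, integration, evaluation) consume and
produce these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

REQUIRED_LAYERS = ("spliced", "unspliced")

#: layers that may legitimately contain negative entries
SIGNED_LAYERS = frozenset({"velocity"})


class BundleError(ValueError):
    """Raised when a ModalityBundle violates its structural contract."""


class AlignmentError(BundleError):
    """Raised when layers cannot be aligned by cell/gene identity."""


def _as_dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


@dataclass
class ModalityBundle:
    """Paired cells x genes layers with shared cell/gene metadata.

    Parameters
    ----------
    layers
        Mapping of layer name to a dense ``(n_cells, n_genes)`` array.
        ``"spliced"`` and ``"unspliced"`` are required and non-negative.
    cell_meta
        Table indexed by unique ``cell_id``; recognised columns include
        ``batch``, ``condition_label``, ``cluster_label``,
        ``is_root_cluster`` (all optional, validated lazily per task).
    gene_meta
        Table indexed by unique ``gene_id``; may carry ``highly_variable``.
    uns
        Free-form metadata (simulation ground truth, size factors, ...).
    """

    layers: Dict[str, np.ndarray]
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    uns: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.layers = {k: _as_dense(v) for k, v in self.layers.items()}
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        for name in REQUIRED_LAYERS:
            if name not in self.layers:
                raise BundleError(f"missing required layer {name!r}")
        shapes = {k: v.shape for k, v in self.layers.items()}
        ref = shapes["spliced"]
        for k, shp in shapes.items():
            if shp != ref:
                raise AlignmentError(
                    f"layer {k!r} has shape {shp}, expected {ref} (as in 'spliced')"
                )
        n_cells, n_genes = ref
        if len(self.cell_meta) != n_cells:
            raise AlignmentError(
                f"cell_meta has {len(self.cell_meta)} rows for {n_cells} cells"
            )
        if len(self.gene_meta) != n_genes:
            raise AlignmentError(
                f"gene_meta has {len(self.gene_meta)} rows for {n_genes} genes"
            )
        if self.cell_meta.index.has_duplicates:
            raise BundleError("duplicate cell_ids")
        if self.gene_meta.index.has_duplicates:
            raise BundleError("duplicate gene_ids")
        for name, mat in self.layers.items():
            if name not in SIGNED_LAYERS and mat.size and mat.min() < 0:
                raise BundleError(f"layer {name!r} contains negative entries")

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.layers["spliced"].shape[0]

    @property
    def n_genes(self) -> int:
        return self.layers["spliced"].shape[1]

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.cell_meta.index)

    @property
    def gene_ids(self) -> np.ndarray:
        return np.asarray(self.gene_meta.index)

    def copy(self) -> "ModalityBundle":
        return ModalityBundle(
            layers={k: v.copy() for k, v in self.layers.items()},
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            uns=dict(self.uns),
        )

    def subset(self, cells=None, genes=None) -> "ModalityBundle":
        """Subset all layers and metadata identically (positional masks/indices)."""
        cells = slice(None) if cells is None else np.asarray(cells)
        genes = slice(None) if genes is None else np.asarray(genes)
        layers = {k: v[cells][:, genes] for k, v in self.layers.items()}
        uns = dict(self.uns)
        for key in ("latent_u", "latent_s", "latent_v"):
            if key in uns:
                uns[key] = uns[key][cells][:, genes]
        return ModalityBundle(
            layers=layers,
            cell_meta=self.cell_meta.iloc[cells] if not isinstance(cells, slice) else self.cell_meta,
            gene_meta=self.gene_meta.iloc[genes] if not isinstance(genes, slice) else self.gene_meta,
            uns=uns,
        )

    def require_columns(self, *cols: str) -> None:
        missing = [c for c in cols if c not in self.cell_meta.columns]
        if missing:
            raise BundleError(
                f"task requires cell_meta columns {missing}; present: "
                f"{list(self.cell_meta.columns)}"
            )


@dataclass
class NeighborGraph:
    """Sparse weighted k-NN adjacency over the cells of a bundle.

    ``adjacency`` is a non-negative ``(n, n)`` sparse matrix with zero
    diagonal; row i holds the edges of cell i.  ``symmetric`` asserts
    ``A == A.T``.
    """

    adjacency: sp.csr_matrix
    k: int
    symmetric: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency)
        a.setdiag(0)
        a.eliminate_zeros()
        self.adjacency = a
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.nnz and a.data.min() < 0:
            raise ValueError("adjacency weights must be non-negative")
        if self.symmetric and (abs(a - a.T)).max() > 1e-9:
            raise ValueError("symmetric flag set but adjacency != adjacency.T")

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def symmetrized(self) -> "NeighborGraph":
        a = self.adjacency.maximum(self.adjacency.T)
        return NeighborGraph(a, k=self.k, symmetric=True, provenance=self.provenance)


@dataclass
class Embedding:
    """An ``(n_cells, K)`` coordinate matrix aligned with bundle cell order."""

    coordinates: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] < 1:
            raise ValueError("coordinates must be 2-D with K >= 1")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates contain non-finite entries")
        self.coordinates = c

    @property
    def K(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class TransitionMatrix:
    """Row-stochastic cell-cell transition operator."""

    P: np.ndarray
    kind: str = "expression"

    def __post_init__(self) -> None:
        P = _as_dense(self.P)
        if P.shape[0] != P.shape[1]:
            raise ValueError("transition matrix must be square")
        if P.size and P.min() < -1e-12:
            raise ValueError("transition matrix has negative entries")
        rows = P.sum(axis=1)
        if P.size and np.abs(rows - 1.0).max() > 1e-9:
            raise ValueError("transition matrix rows must sum to 1 within 1e-9")
        self.P = np.clip(P, 0.0, None)

    @property
    def n(self) -> int:
        return self.P.shape[0]


def make_bundle(
    spliced,
    unspliced,
    cell_ids=None,
    gene_ids=None,
    *,
    extra_layers: Optional[Dict[str, np.ndarray]] = None,
    cell_meta: Optional[pd.DataFrame] = None,
    gene_meta: Optional[pd.DataFrame] = None,
    uns: Optional[Dict[str, Any]] = None,
) -> ModalityBundle:
    """Assemble a bundle from bare matrices, generating ids when absent."""
    spliced = _as_dense(spliced)
    n, d = spliced.shape
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]
    if gene_ids is None:
        gene_ids = [f"gene_{j}" for j in range(d)]
    if cell_meta is None:
        cell_meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    else:
        cell_meta = cell_meta.copy()
        cell_meta.index = pd.Index(cell_ids, name="cell_id")
    if gene_meta is None:
        gene_meta = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    else:
        gene_meta = gene_meta.copy()
        gene_meta.index = pd.Index(gene_ids, name="gene_id")
    layers = {"spliced": spliced, "unspliced": _as_dense(unspliced)}
    if extra_layers:
        layers.update({k: _as_dense(v) for k, v in extra_layers.items()})
    return ModalityBundle(layers=layers, cell_meta=cell_meta, gene_meta=gene_meta, uns=uns or {})
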