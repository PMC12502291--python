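"""Expression dataset container and format readers/writers.

The central object is :class:`ExpressionDataset`, a light wrapper around a
dense cells-by-genes matrix with cell/gene identifiers, optional per-cell
labels, clusters and spatial coordinates, and an ``origin`` tag
distinguishing the annotated scRNA-seq reference from the spatial query.
AnnData is used for h5ad/MTX round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

import anndata as ad

REFERENCE = "reference"
QUERY = "query"


@dataclass
class ExpressionDataset:
    """One cells-by-genes expression matrix with annotations.

    ``matrix`` holds raw counts on load; the preprocessing transforms
    (library-size normalization, log, z-scaling) return new instances with
    the ``stage`` field advanced so misuse (e.g. selecting HVGs on raw
    counts) is caught early.
    """

    matrix: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    origin: str
    labels: Optional[np.ndarray] = None
    clusters: Optional[np.ndarray] = None
    coords: Optional[np.ndarray] = None
    stage: str = "raw"  # raw -> normalized -> scaled
    layers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.origin not in (REFERENCE, QUERY):
            raise ValueError(f"origin must be '{REFERENCE}' or '{QUERY}', got {self.origin!r}")
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x genes)")
        if self.matrix.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if self.stage == "raw":
            if not np.all(np.isfinite(self.matrix)):
                raise ValueError("raw matrix contains non-finite entries")
            if self.matrix.min() < 0:
                raise ValueError("raw matrix contains negative entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.n_cells:
                raise ValueError("labels must cover every cell")
        if self.clusters is not None:
            self.clusters = np.asarray(self.clusters, dtype=object)
            if len(self.clusters) != self.n_cells:
                raise ValueError("clusters must cover every cell")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n_cells, 2):
                raise ValueError("coords must be n_cells x 2")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Column indices of the given genes, error on missing ids."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:10]}")
        return np.array([lookup[g] for g in genes], dtype=np.int64)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(genes)
        return replace(
            self,
            matrix=self.matrix[:, idx],
            gene_ids=self.gene_ids[idx],
            layers={k: v[:, idx] for k, v in self.layers.items()},
        )

    def with_matrix(self, matrix: np.ndarray, stage: str) -> "ExpressionDataset":
        return replace(self, matrix=matrix, stage=stage)

    # -- interchange ---------------------------------------------------

    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell_id"))
        if self.labels is not None:
            obs["cell_type"] = pd.Categorical(self.labels.astype(str))
        if self.clusters is not None:
            obs["cluster"] = pd.Categorical(self.clusters.astype(str))
        adata = ad.AnnData(
            X=self.matrix.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id")),
        )
        if self.coords is not None:
            adata.obsm["spatial"] = self.coords.copy()
        for name, layer in self.layers.items():
            adata.layers[name] = layer.copy()
        adata.uns["origin"] = self.origin
        adata.uns["stage"] = self.stage
        return adata

    @classmethod
    def from_anndata(
        cls,
        adata: ad.AnnData,
        origin: str,
        label_key: Optional[str] = None,
        stage: str = "raw",
    ) -> "ExpressionDataset":
        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        labels = None
        if label_key is not None:
            if label_key not in adata.obs:
                raise KeyError(f"label key {label_key!r} not in obs")
            labels = adata.obs[label_key].astype(str).to_numpy()
        coords = adata.obsm.get("spatial")
        return cls(
            matrix=np.asarray(X, dtype=float),
            cell_ids=adata.obs_names.to_numpy(),
            gene_ids=adata.var_names.to_numpy(),
            origin=origin,
            labels=labels,
            coords=None if coords is None else np.asarray(coords)[:, :2],
            stage=stage,
        )


def read_h5ad(path, origin: str, label_key: Optional[str] = None) -> ExpressionDataset:
    return ExpressionDataset.from_anndata(ad.read_h5ad(path), origin, label_key)


def read_mtx(
    mtx_path,
    genes_path,
    barcodes_path,
    origin: str,
    labels: Optional[Sequence[str]] = None,
) -> ExpressionDataset:
    """MatrixMarket counts (cells x genes) with gene/barcode TSVs."""
    import scipy.io as sio

    X = sio.mmread(mtx_path)
    if sp.issparse(X):
        X = X.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy()
    return ExpressionDataset(
        matrix=np.asarray(X, dtype=float),
        cell_ids=barcodes,
        gene_ids=genes,
        origin=origin,
        labels=None if labels is None else np.asarray(labels, dtype=object),
    )


def read_csv(path, origin: str, label_column: Optional[str] = None) -> ExpressionDataset:
    """Dense CSV, cells as rows, genes as columns, first column cell ids."""
    df = pd.read_csv(path, index_col=0)
    labels = None
    if label_column is not None:
        labels = df.pop(label_column).astype(str).to_numpy()
    return ExpressionDataset(
        matrix=df.to_numpy(dtype=float),
        cell_ids=df.index.to_numpy(),
        gene_ids=df.columns.to_numpy(),
        origin=origin,
        labels=labels,
    )


def write_processed_h5ad(dataset: ExpressionDataset, selection, path) -> None:
    """Persist a processed dataset with selection lists in ``.uns``."""
    adata = dataset.to_anndata()
    if selection is not None:
        adata.uns["gene_selection"] = {
            "node_genes": list(map(str, selection.node_genes)),
            "feature_genes": list(map(str, selection.feature_genes)),
            "hvgs_ref": list(map(str, selection.hvgs_ref)),
            "hvgs_query": list(map(str, selection.hvgs_query)),
        }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    adata.write_h5ad(path)
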