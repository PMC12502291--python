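"""Heterogeneous cell-gene graph over the two processed datasets.

Five relation types connect two node types:

* ``cell_self_loop`` / ``gene_self_loop`` — every node to itself, so each
  update keeps a direct path to the node's previous embedding;
* ``cell_similar_to_cell`` — directed k-nearest-neighbor edges on the
  scaled feature vectors, built within each dataset separately; in the
  labeled reference, edges joining cells of different types are removed;
* ``gene_expressed_by_cell`` / ``cell_express_gene`` — one edge in each
  direction for every (cell, gene-node) pair with positive normalized
  expression.

Edges are stored 0-based with cells indexed reference-first, then query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import ExpressionDataset, REFERENCE, QUERY
from .preprocess import GeneSelection

RELATIONS = (
    "cell_self_loop",
    "gene_self_loop",
    "cell_similar_to_cell",
    "gene_expressed_by_cell",
    "cell_express_gene",
)


@dataclass
class HeteroGraph:
    cell_ids: np.ndarray          # N ids, reference block first
    cell_origin: np.ndarray       # N strings in {reference, query}
    gene_ids: np.ndarray          # s node-gene ids
    edges: Dict[str, np.ndarray]  # relation -> (E, 2) int array (src, dst)
    cell_features: np.ndarray     # N x p scaled features
    feature_genes: List[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def ref_mask(self) -> np.ndarray:
        return self.cell_origin == REFERENCE

    @property
    def query_mask(self) -> np.ndarray:
        return self.cell_origin == QUERY

    def expression_csr(self) -> sp.csr_matrix:
        """Cell-major incidence of cell_express_gene as an N x s CSR."""
        e = self.edges["cell_express_gene"]
        return sp.csr_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(self.n_cells, self.n_genes)
        )

    def validate(self) -> None:
        """Check the structural invariants; raise on violation."""
        n, s = self.n_cells, self.n_genes
        csl = self.edges["cell_self_loop"]
        gsl = self.edges["gene_self_loop"]
        assert len(csl) == n and np.array_equal(csl[:, 0], csl[:, 1])
        assert len(gsl) == s and np.array_equal(gsl[:, 0], gsl[:, 1])
        ge = self.edges["gene_expressed_by_cell"]
        ce = self.edges["cell_express_gene"]
        assert len(ge) == len(ce)
        fwd = set(map(tuple, ce))
        rev = set((g, c) for g, c in ge)
        assert fwd == set((c, g) for g, c in rev)
        knn = self.edges["cell_similar_to_cell"]
        if len(knn):
            assert np.all(self.cell_origin[knn[:, 0]] == self.cell_origin[knn[:, 1]])

    # -- persistence ---------------------------------------------------

    def save(self, directory) -> None:
        """Edge-list archive: one TSV per relation plus node manifests."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rel in RELATIONS:
            pd.DataFrame(self.edges[rel], columns=["src", "dst"]).to_csv(
                directory / f"edges_{rel}.tsv", sep="\t", index=False
            )
        pd.DataFrame(
            {"cell_id": self.cell_ids.astype(str), "origin": self.cell_origin}
        ).to_csv(directory / "cells.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": self.gene_ids.astype(str)}).to_csv(
            directory / "genes.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            self.cell_features, columns=[str(g) for g in self.feature_genes]
        ).to_csv(directory / "cell_features.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory) -> "HeteroGraph":
        directory = Path(directory)
        cells = pd.read_csv(directory / "cells.tsv", sep="\t")
        genes = pd.read_csv(directory / "genes.tsv", sep="\t")
        feats = pd.read_csv(directory / "cell_features.tsv", sep="\t")
        edges = {}
        for rel in RELATIONS:
            df = pd.read_csv(directory / f"edges_{rel}.tsv", sep="\t")
            edges[rel] = df.to_numpy(dtype=np.int64).reshape(-1, 2)
        return cls(
            cell_ids=cells["cell_id"].to_numpy(dtype=object),
            cell_origin=cells["origin"].to_numpy(dtype=object),
            gene_ids=genes["gene_id"].to_numpy(dtype=object),
            edges=edges,
            cell_features=feats.to_numpy(dtype=float),
            feature_genes=list(feats.columns),
        )


def build_expression_edges(
    dataset: ExpressionDataset,
    node_genes: Sequence[str],
    threshold: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cell-gene edges where normalized expression exceeds ``threshold``.

    Returns (cell_express_gene, gene_expressed_by_cell) arrays with local
    cell indices and gene indices into ``node_genes``.
    """
    if dataset.stage != "normalized":
        raise ValueError("expression edges are built on normalized (pre-scaled) data")
    sub = dataset.subset_genes(list(node_genes))
    # log1p-normalized data: a zero count maps to log(pseudocount); with
    # pseudocount 1 that is exactly 0, so "> 0" means "expressed".
    cells, genes = np.nonzero(sub.matrix > threshold)
    silent = np.setdiff1d(np.arange(len(node_genes)), np.unique(genes))
    if silent.size:
        warnings.warn(
            f"{silent.size} gene nodes expressed in no cell of the "
            f"{dataset.origin} dataset",
            stacklevel=2,
        )
    ceg = np.column_stack([cells, genes]).astype(np.int64)
    gec = np.column_stack([genes, cells]).astype(np.int64)
    return ceg, gec


def build_cell_knn_edges(
    features: np.ndarray,
    origin: np.ndarray,
    k: int = 5,
    labels: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Directed kNN edges (cell -> neighbor) within each dataset.

    Euclidean distance on the feature vectors, self excluded, ties broken
    by cell index (stable sort).  When ``labels`` is given (the reference),
    edges whose endpoints carry different labels are removed.
    """
    from scipy.spatial.distance import cdist

    if k < 1:
        raise ValueError("k must be >= 1")
    features = np.asarray(features, dtype=np.float64)
    origin = np.asarray(origin)
    edges = []
    for tag in (REFERENCE, QUERY):
        idx = np.flatnonzero(origin == tag)
        if idx.size == 0:
            continue
        if idx.size <= k:
            raise ValueError(
                f"{tag} dataset has {idx.size} cells, need more than k={k}"
            )
        D = cdist(features[idx], features[idx])
        np.fill_diagonal(D, np.inf)  # self connectivity lives in cell_self_loop
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        for row in range(idx.size):
            for c in order[row]:
                edges.append((idx[row], idx[c]))
    out = np.array(edges, dtype=np.int64).reshape(-1, 2)
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        ref = origin == REFERENCE
        keep = np.ones(len(out), dtype=bool)
        for i, (a, b) in enumerate(out):
            if ref[a] and labels[a] != labels[b]:
                keep[i] = False
        out = out[keep]
    return out


def assemble_graph(
    ref: ExpressionDataset,
    query: ExpressionDataset,
    selection: GeneSelection,
    k: int = 5,
    expression_threshold: float = 0.0,
) -> HeteroGraph:
    """Build the full five-relation graph from two normalized datasets.

    ``ref`` and ``query`` must be at the normalized stage; scaling to the
    feature genes happens here so expression edges can use pre-scaled
    positivity.
    """
    from .preprocess import scale_features

    if ref.origin != REFERENCE or query.origin != QUERY:
        raise ValueError("expected one reference and one query dataset")
    if not selection.node_genes:
        raise ValueError("node_genes is empty")

    node_genes = list(selection.node_genes)
    n_ref, n_query = ref.n_cells, query.n_cells
    n = n_ref + n_query
    s = len(node_genes)

    ceg_r, gec_r = build_expression_edges(ref, node_genes, expression_threshold)
    ceg_q, gec_q = build_expression_edges(query, node_genes, expression_threshold)
    ceg_q = ceg_q + np.array([n_ref, 0])
    gec_q = gec_q + np.array([0, n_ref])
    ceg = np.vstack([ceg_r, ceg_q])
    gec = np.vstack([gec_r, gec_q])

    expressed = np.zeros(n, dtype=bool)
    expressed[ceg[:, 0]] = True
    if not expressed.all():
        bad = np.flatnonzero(~expressed)
        ids = np.concatenate([ref.cell_ids, query.cell_ids])[bad[:5]]
        raise ValueError(
            f"{(~expressed).sum()} cells express no gene node "
            f"(e.g. {list(ids)}); every cell must connect to the gene layer"
        )

    ref_scaled = scale_features(ref, selection.feature_genes)
    query_scaled = scale_features(query, selection.feature_genes)
    features = np.vstack([ref_scaled.matrix, query_scaled.matrix])
    origin = np.array([REFERENCE] * n_ref + [QUERY] * n_query, dtype=object)

    labels = None
    if ref.labels is not None:
        labels = np.concatenate([ref.labels, np.array(["__query__"] * n_query, dtype=object)])
    knn = build_cell_knn_edges(features, origin, k=k, labels=labels)

    arange_n = np.arange(n, dtype=np.int64)
    arange_s = np.arange(s, dtype=np.int64)
    edges = {
        "cell_self_loop": np.column_stack([arange_n, arange_n]),
        "gene_self_loop": np.column_stack([arange_s, arange_s]),
        "cell_similar_to_cell": knn,
        "gene_expressed_by_cell": gec,
        "cell_express_gene": ceg,
    }
    return HeteroGraph(
        cell_ids=np.concatenate([ref.cell_ids, query.cell_ids]),
        cell_origin=origin,
        gene_ids=np.asarray(node_genes, dtype=object),
        edges=edges,
        cell_features=features,
        feature_genes=list(selection.feature_genes),
    )
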