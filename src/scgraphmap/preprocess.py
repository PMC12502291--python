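"""Preprocessing: normalization, HVG/DEG selection, gene sets, scaling.

The recipe mirrors the standard single-cell workflow: per-cell library-size
normalization to a common total, log1p-style transform, dispersion-based
highly-variable-gene selection (skipped for small spatial gene panels),
Leiden pre-clustering of the unlabeled query, one-vs-rest Welch t-test DEGs
ranked by Benjamini-Hochberg adjusted p-value, and per-gene z-scaling.

Gene-node and cell-feature gene sets are derived from the per-dataset
selections: the graph's gene nodes are the intersection across datasets of
(HVGs union DEGs), while the per-cell input vector uses the union of all
DEG lists restricted to genes shared by both datasets, so reference and
query cells have identical input dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset, QUERY


@dataclass
class GeneSelection:
    """Per-dataset gene selections and the derived shared gene sets."""

    hvgs_ref: List[str]
    hvgs_query: List[str]
    degs_ref: Dict[str, List[str]] = field(default_factory=dict)
    degs_query: Dict[str, List[str]] = field(default_factory=dict)
    node_genes: List[str] = field(default_factory=list)
    feature_genes: List[str] = field(default_factory=list)


def normalize_log(
    raw: ExpressionDataset,
    target_sum: float = 1e4,
    pseudocount: float = 1.0,
) -> ExpressionDataset:
    """Library-size normalize each cell to ``target_sum``, then log.

    Each entry becomes ``log(count * target_sum / cell_total + pseudocount)``.
    """
    if raw.stage != "raw":
        raise ValueError(f"expected raw counts, got stage={raw.stage!r}")
    if target_sum <= 0 or pseudocount <= 0:
        raise ValueError("target_sum and pseudocount must be positive")
    X = np.asarray(raw.matrix, dtype=np.float64)
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts cannot be normalized: "
            f"{list(raw.cell_ids[zero[:5]])}"
        )
    norm = np.log(X * (target_sum / totals[:, None]) + pseudocount)
    out = raw.with_matrix(norm, stage="normalized")
    out.layers = dict(raw.layers)
    out.layers["raw"] = X
    return out


def select_hvgs(norm: ExpressionDataset, n_top: int = 2000) -> List[str]:
    """Dispersion-ranked highly variable genes on log-normalized data.

    Spatial panels at or under ``n_top`` genes skip selection and keep
    every gene, matching common practice for targeted gene panels.
    """
    if norm.stage == "raw":
        raise ValueError("select_hvgs requires normalized data")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if norm.n_cells < 2:
        raise ValueError("need at least 2 cells for HVG selection")
    if norm.n_genes <= n_top:
        return list(norm.gene_ids)
    import scanpy as sc

    adata = norm.to_anndata()
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    return list(adata.var_names[adata.var["highly_variable"].to_numpy()])


def precluster_query(
    norm: ExpressionDataset,
    resolution: float = 0.4,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Leiden pre-clustering of the query for per-cluster DEG detection."""
    if norm.origin != QUERY:
        raise ValueError("pre-clustering is applied to the query dataset")
    if norm.n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    import scanpy as sc

    adata = norm.to_anndata()
    sc.pp.pca(adata, n_comps=min(50, norm.n_cells - 1, norm.n_genes - 1), random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, norm.n_cells - 1), random_state=seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            key_added="cluster",
            random_state=seed,
            flavor="leidenalg",
        )
    return adata.obs["cluster"].astype(str).to_numpy()


def rank_degs(
    norm: ExpressionDataset,
    groups: Sequence[str],
    n_top: int = 50,
    alpha: float = 0.05,
) -> Dict[str, List[str]]:
    """One-vs-rest Welch t-test DEGs per group.

    P-values are Benjamini-Hochberg adjusted within each group's test
    family; genes with adjusted p < ``alpha`` are kept, ranked ascending by
    adjusted p (ties by descending |t|, then gene id) and truncated to
    ``n_top``.
    """
    if norm.stage == "raw":
        raise ValueError("rank_degs requires normalized data")
    groups = np.asarray(groups, dtype=object)
    if len(groups) != norm.n_cells:
        raise ValueError("groups must cover every cell")
    X = norm.matrix
    result: Dict[str, List[str]] = {}
    for g in _unique_keep_order(groups):
        mask = groups == g
        n_in = int(mask.sum())
        if n_in < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        if (~mask).sum() < 2:
            # a single dominant group leaves no rest to test against
            result[str(g)] = []
            continue
        t, p = scipy.stats.ttest_ind(X[mask], X[~mask], axis=0, equal_var=False)
        t = np.nan_to_num(t, nan=0.0)
        p = np.where(np.isnan(p), 1.0, p)
        padj = multipletests(p, method="fdr_bh")[1]
        keep = np.flatnonzero(padj < alpha)
        order = sorted(
            keep,
            key=lambda i: (padj[i], -abs(t[i]), str(norm.gene_ids[i])),
        )
        result[str(g)] = [str(norm.gene_ids[i]) for i in order[:n_top]]
    return result


def _unique_keep_order(values: np.ndarray) -> List:
    seen = set()
    out = []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def build_gene_sets(
    ref: ExpressionDataset,
    query: ExpressionDataset,
    hvgs_ref: Sequence[str],
    hvgs_query: Sequence[str],
    degs_ref: Dict[str, List[str]],
    degs_query: Dict[str, List[str]],
) -> GeneSelection:
    """Derive graph gene nodes and cell-feature genes from selections.

    node_genes = (HVG_ref | DEG_ref) & (HVG_query | DEG_query) & shared;
    feature_genes = union of every DEG list & shared genes.  Output order
    follows the reference dataset's gene order for determinism.
    """
    shared = set(ref.gene_ids) & set(query.gene_ids)
    sel_ref = set(hvgs_ref).union(*degs_ref.values()) if degs_ref else set(hvgs_ref)
    sel_query = (
        set(hvgs_query).union(*degs_query.values()) if degs_query else set(hvgs_query)
    )
    node = sel_ref & sel_query & shared
    if not node:
        raise ValueError(
            "empty gene-node intersection: "
            f"reference selected {len(sel_ref)} genes, query selected "
            f"{len(sel_query)}, shared gene space {len(shared)}"
        )
    feat = set()
    for lists in (degs_ref, degs_query):
        for genes in lists.values():
            feat.update(genes)
    feat &= shared
    if not feat:
        # degenerate: no DEG survives filtering; fall back to node genes
        feat = set(node)
    ref_order = {g: i for i, g in enumerate(ref.gene_ids)}
    return GeneSelection(
        hvgs_ref=list(hvgs_ref),
        hvgs_query=list(hvgs_query),
        degs_ref={k: list(v) for k, v in degs_ref.items()},
        degs_query={k: list(v) for k, v in degs_query.items()},
        node_genes=sorted(node, key=lambda g: ref_order[g]),
        feature_genes=sorted(feat, key=lambda g: ref_order[g]),
    )


def scale_features(
    norm: ExpressionDataset,
    gene_subset: Optional[Sequence[str]] = None,
) -> ExpressionDataset:
    """Per-gene z-score over the dataset's cells (population std).

    Constant genes map to all-zero columns.
    """
    if norm.stage == "raw":
        raise ValueError("scale_features requires normalized data")
    ds = norm if gene_subset is None else norm.subset_genes(list(gene_subset))
    X = ds.matrix
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, sd == 0] = 0.0
    return ds.with_matrix(Z, stage="scaled")
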