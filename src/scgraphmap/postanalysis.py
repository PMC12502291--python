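"""Post-hoc analyses on the trained model.

* Unknown-cell detection: a query cell is rejected as "unknown" when its
  prediction confidence is below the median over all query cells AND its
  predicted type is globally far from the reference — the per-type
  distance being the average, over the type's query cells, of the mean
  Euclidean distance to each cell's nearest reference cells after joint
  PCA of the cell embeddings.  Types listed as low-confidence are rejected
  on the confidence rule alone.
* Gene modules: Leiden communities on the last-layer gene embeddings.
* Gene importance: per cell type, the mean attention a gene receives from
  the type's expressing cells.
* Gene similarity: cosine similarity of last-layer gene embeddings.
* Evaluation: accuracy, macro F1 and weighted F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .trainer import PredictionResult


@dataclass
class UnknownConfig:
    distance_threshold: float = 4.0
    pca_dim: int = 50
    n_neighbors: int = 5
    low_confidence_types: Optional[List[str]] = None

    def __post_init__(self):
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")
        if self.pca_dim < 1:
            raise ValueError("pca_dim must be >= 1")


@dataclass
class GeneModuleSet:
    gene_ids: np.ndarray
    module_ids: np.ndarray        # per gene, 0..M-1 ordered by size desc
    n_modules: int
    type_means: Optional[pd.DataFrame] = None  # module x cell type mean expression

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids.astype(str), "module": self.module_ids}
        )


@dataclass
class MetricReport:
    accuracy: float
    macro_f1: float
    weighted_f1: float
    per_class: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> Dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
        }


def celltype_distance(
    query_emb: np.ndarray,
    query_types: np.ndarray,
    ref_emb: np.ndarray,
    cfg: UnknownConfig = UnknownConfig(),
    seed: int = 0,
) -> Dict[str, float]:
    """Average query-to-reference embedding distance per predicted type.

    Both embedding sets are jointly reduced by PCA before the
    nearest-neighbor search.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    if len(query_emb) == 0 or len(ref_emb) == 0:
        raise ValueError("both query and reference embeddings must be non-empty")
    joint = np.vstack([ref_emb, query_emb]).astype(np.float64)
    n_comp = min(cfg.pca_dim, joint.shape[1], joint.shape[0])
    if n_comp < joint.shape[1]:
        pca = PCA(n_components=n_comp, random_state=seed)
        joint = pca.fit_transform(joint)
    ref_p = joint[: len(ref_emb)]
    query_p = joint[len(ref_emb) :]

    k = min(cfg.n_neighbors, len(ref_emb))
    nn = NearestNeighbors(n_neighbors=k).fit(ref_p)
    dist, _ = nn.kneighbors(query_p)
    per_cell = dist.mean(axis=1)

    query_types = np.asarray(query_types, dtype=object)
    out: Dict[str, float] = {}
    for t in sorted(map(str, set(query_types))):
        mask = query_types == t
        if mask.any():
            out[t] = float(per_cell[mask].mean())
    return out


def detect_unknown(
    pred: PredictionResult,
    distances: Dict[str, float],
    cfg: UnknownConfig = UnknownConfig(),
) -> np.ndarray:
    """Two-rule unknown flags (confidence below median AND distant type)."""
    median = float(np.median(pred.max_prob))
    low_conf = pred.max_prob < median
    low_types = set(cfg.low_confidence_types or [])
    flagged = np.zeros(len(pred.labels), dtype=bool)
    for i, (lab, lc) in enumerate(zip(pred.labels, low_conf)):
        if not lc:
            continue
        lab = str(lab)
        if lab in low_types or distances.get(lab, 0.0) > cfg.distance_threshold:
            flagged[i] = True
    return flagged


def extract_gene_modules(
    gene_emb: np.ndarray,
    gene_ids: Sequence[str],
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> GeneModuleSet:
    """Leiden partition of a kNN graph over the gene embeddings."""
    import igraph
    import leidenalg

    gene_emb = np.asarray(gene_emb, dtype=np.float64)
    n = len(gene_emb)
    if n < 2:
        raise ValueError("need at least 2 gene nodes")
    from sklearn.neighbors import NearestNeighbors

    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(gene_emb)
    _, nbr = nn.kneighbors(gene_emb)
    edges = set()
    for i in range(n):
        picked = [int(j) for j in nbr[i] if int(j) != i][:k]
        for j in picked:
            edges.add((min(i, j), max(i, j)))
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.array(part.membership)
    # relabel module ids by size, largest first; ties by original id
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    modules = np.array([remap[r] for r in raw], dtype=np.int64)
    return GeneModuleSet(
        gene_ids=np.asarray(gene_ids, dtype=object),
        module_ids=modules,
        n_modules=len(ids),
    )


def module_type_means(
    modules: GeneModuleSet,
    expression: np.ndarray,
    gene_ids: Sequence[str],
    cell_types: np.ndarray,
) -> pd.DataFrame:
    """Mean normalized expression of each module in each cell type."""
    gene_ids = list(map(str, gene_ids))
    col = {g: i for i, g in enumerate(gene_ids)}
    idx = [col[str(g)] for g in modules.gene_ids]
    sub = np.asarray(expression)[:, idx]
    cell_types = np.asarray(cell_types, dtype=object)
    rows = []
    types = sorted(map(str, set(cell_types)))
    for m in range(modules.n_modules):
        gmask = modules.module_ids == m
        row = {}
        for t in types:
            cmask = cell_types == t
            row[t] = float(sub[np.ix_(cmask, gmask)].mean())
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.RangeIndex(modules.n_modules, name="module"))
    modules.type_means = df
    return df


def gene_importance(
    attention: sp.csr_matrix,
    cell_types: np.ndarray,
    gene_ids: Sequence[str],
) -> pd.DataFrame:
    """Cell-type-by-gene mean attention over expressing cells.

    ``attention`` is the cells-by-genes CSR of normalized attention
    weights; zeros mark non-expressing pairs and are excluded from the
    mean, so every entry is a convex combination of attention weights.
    """
    cell_types = np.asarray(cell_types, dtype=object)
    support = attention.copy()
    support.data = np.ones_like(support.data)
    rows = {}
    for t in sorted(map(str, set(cell_types))):
        mask = cell_types == t
        if not mask.any():
            continue
        att_sum = np.asarray(attention[mask].sum(axis=0)).ravel()
        n_expr = np.asarray(support[mask].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore"):
            mean = np.where(n_expr > 0, att_sum / np.maximum(n_expr, 1), 0.0)
        rows[t] = mean
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(map(str, gene_ids))
    )


def gene_similarity(
    gene_emb: np.ndarray,
    gene_ids: Sequence[str],
    pairs: Sequence[Tuple[str, str]],
) -> np.ndarray:
    """Cosine similarity of last-layer embeddings for gene-id pairs."""
    lookup = {str(g): i for i, g in enumerate(gene_ids)}
    out = np.empty(len(pairs))
    for n, (a, b) in enumerate(pairs):
        for g in (a, b):
            if str(g) not in lookup:
                raise KeyError(f"gene {g!r} is not a gene node")
        va = np.asarray(gene_emb[lookup[str(a)]], dtype=np.float64)
        vb = np.asarray(gene_emb[lookup[str(b)]], dtype=np.float64)
        denom = np.linalg.norm(va) * np.linalg.norm(vb)
        out[n] = float(va @ vb / denom) if denom else 0.0
    return out


def compute_metrics(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
) -> MetricReport:
    """Accuracy, macro F1 and weighted F1 over the union class universe.

    Classes present in only one of the two vectors receive F1 = 0 on the
    missing side; macro F1 averages over classes present in the truth plus
    spurious predicted classes, and weighted F1 weights by truth
    proportions (spurious classes then carry zero weight).
    """
    from sklearn.metrics import f1_score, precision_recall_fscore_support

    t = np.asarray(list(map(str, true_labels)), dtype=object)
    p = np.asarray(list(map(str, pred_labels)), dtype=object)
    if len(t) == 0 or len(t) != len(p):
        raise ValueError("label vectors must be non-empty and equal length")
    labels = sorted(set(t) | set(p))
    accuracy = float((t == p).mean())
    prec, rec, f1, support = precision_recall_fscore_support(
        t, p, labels=labels, zero_division=0
    )
    macro = float(f1_score(t, p, labels=labels, average="macro", zero_division=0))
    weighted = float(f1_score(t, p, labels=labels, average="weighted", zero_division=0))
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=pd.Index(labels, name="class"),
    )
    return MetricReport(
        accuracy=accuracy, macro_f1=macro, weighted_f1=weighted, per_class=per_class
    )
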