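"""Heterogeneous message-passing encoder, graph-attention classifier, loss.

The encoder propagates information over the five-relation cell-gene graph.
Every relation of the same type shares one weight matrix per layer.  With
``sigma`` a LeakyReLU and ``LN`` non-affine layer normalization:

* layer 0:  ``h_i_c = LN(sigma(W_c0 x_i + b_c0))`` for cells and
  ``h_k_g = LN(sigma(mean_{i in expressing cells} W_cg0 x_i + b_g0))`` for
  genes, where ``x_i`` is the cell's scaled expression over the feature
  genes;
* layers 1..L: each node update sums, over the relations incident to its
  node type, the mean of relation-transformed neighbor embeddings, plus a
  self term and a node-type bias, then applies ``sigma`` and ``LN``.

The classifier scores each expression edge (cell i, gene j) with
``e_ij = LeakyReLU(v . [W_c h_i || W_g h_j])``, softmax-normalizes the
scores over each cell's expressed genes into attention weights, and emits
logits as the attention-weighted sum of ``W_g h_j`` plus an output bias.
Class probabilities are the row softmax of the logits.

The training loss is a class-weighted cross entropy (weights proportional
to 1/sqrt(class size)) with an L2 penalty on the weight matrices, blended
with a label-smoothing term (coefficient ``epsilon``).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse as sp

from ._autodiff import Tensor, attention_matmul
from .hetgraph import HeteroGraph

__all__ = [
    "ModelConfig",
    "ModelState",
    "GraphTensors",
    "ForwardResult",
    "forward",
    "classification_loss",
    "class_weights",
]


@dataclass
class ModelConfig:
    hidden_dim: int = 512
    n_layers: int = 2
    leaky_slope: float = 0.05
    weight_decay: float = 0.01      # lambda on the L2 penalty
    label_smoothing: float = 0.1    # epsilon
    smoothing_sign: str = "standard"  # "standard" | "printed"
    ln_eps: float = 1e-5
    dtype: str = "float32"
    init_seed: int = 0

    def np_dtype(self):
        return np.dtype(self.dtype)


class ModelState:
    """All learnable parameters plus the layer configuration."""

    def __init__(self, config: ModelConfig, n_features: int, n_classes: int):
        if config.n_layers < 1:
            raise ValueError("need at least one hidden layer")
        self.config = config
        self.n_features = int(n_features)
        self.n_classes = int(n_classes)
        self.params: Dict[str, Tensor] = {}
        rng = np.random.default_rng(config.init_seed)
        d, p, C = config.hidden_dim, n_features, n_classes
        dt = config.np_dtype()

        def xavier(fan_in, fan_out, shape=None):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            shape = shape or (fan_in, fan_out)
            return rng.uniform(-limit, limit, size=shape).astype(dt)

        P = self.params
        P["w_c0"] = Tensor(xavier(p, d), requires_grad=True)
        P["w_cg0"] = Tensor(xavier(p, d), requires_grad=True)
        P["b_c0"] = Tensor(np.zeros(d, dtype=dt), requires_grad=True)
        P["b_g0"] = Tensor(np.zeros(d, dtype=dt), requires_grad=True)
        for l in range(1, config.n_layers + 1):
            for name in ("w_csim", "w_gec", "w_cself", "w_ceg", "w_gself"):
                P[f"{name}_{l}"] = Tensor(xavier(d, d), requires_grad=True)
            P[f"b_c_{l}"] = Tensor(np.zeros(d, dtype=dt), requires_grad=True)
            P[f"b_g_{l}"] = Tensor(np.zeros(d, dtype=dt), requires_grad=True)
        P["w_att_c"] = Tensor(xavier(d, C), requires_grad=True)
        P["w_att_g"] = Tensor(xavier(d, C), requires_grad=True)
        P["v"] = Tensor(xavier(2 * C, 1, shape=(2 * C,)), requires_grad=True)
        P["b_out"] = Tensor(np.zeros(C, dtype=dt), requires_grad=True)

    def weight_names(self) -> List[str]:
        """Parameters entering the L2 penalty (weights and v, not biases)."""
        return [k for k in self.params if k.startswith("w_") or k == "v"]

    def copy_arrays(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = arrays[k].copy()

    # -- checkpoint archive -------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "n_features": self.n_features,
            "n_classes": self.n_classes,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(meta))
            for k, t in self.params.items():
                buf = io.BytesIO()
                np.save(buf, t.data)
                zf.writestr(f"params/{k}.npy", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ModelState":
        with zipfile.ZipFile(path, "r") as zf:
            meta = json.loads(zf.read("config.json"))
            state = cls(
                ModelConfig(**meta["config"]), meta["n_features"], meta["n_classes"]
            )
            for k in state.params:
                arr = np.load(io.BytesIO(zf.read(f"params/{k}.npy")))
                state.params[k].data = arr
        return state


@dataclass
class GraphTensors:
    """Graph structure precompiled into aggregation operators.

    Each sparse matrix maps source-node rows to receiver rows and encodes
    the 1/|N_r| mean over the receiver's neighbors; zero-degree receivers
    keep an all-zero row, i.e. the empty-neighborhood sum contributes
    nothing.
    """

    X: np.ndarray                 # N x p scaled cell features
    A_csim: sp.csr_matrix         # N x N  cell <- cell (similar-to)
    A_gec: sp.csr_matrix          # N x s  cell <- gene (gene_expressed_by_cell)
    A_ceg: sp.csr_matrix          # s x N  gene <- cell (cell_express_gene)
    expr_indptr: np.ndarray       # cell-major CSR over expression edges
    expr_gene_idx: np.ndarray     # gene index per expression edge
    expr_cell_idx: np.ndarray     # cell index per expression edge
    n_cells: int
    n_genes: int

    @classmethod
    def from_graph(cls, graph: HeteroGraph, dtype=np.float32) -> "GraphTensors":
        n, s = graph.n_cells, graph.n_genes

        def mean_agg(edges, n_src, n_dst):
            # edges rows are (src, dst); receiver = dst
            if len(edges) == 0:
                return sp.csr_matrix((n_dst, n_src), dtype=dtype)
            A = sp.csr_matrix(
                (np.ones(len(edges), dtype=np.float64), (edges[:, 1], edges[:, 0])),
                shape=(n_dst, n_src),
            )
            A.sum_duplicates()
            A.data[:] = 1.0  # duplicate edges collapse before the mean
            deg = np.asarray(A.sum(axis=1)).ravel()
            deg[deg == 0] = 1.0
            A = sp.diags(1.0 / deg) @ A
            A = A.astype(dtype).tocsr()
            # dense gemm beats sparse matvecs once the operator is this full
            if A.nnz > 0.05 * n_src * n_dst:
                return np.ascontiguousarray(A.toarray())
            return A

        A_csim = mean_agg(graph.edges["cell_similar_to_cell"], n, n)
        A_gec = mean_agg(graph.edges["gene_expressed_by_cell"], s, n)
        A_ceg = mean_agg(graph.edges["cell_express_gene"], n, s)

        expr = graph.expression_csr()
        expr.sum_duplicates()
        return cls(
            X=np.ascontiguousarray(graph.cell_features, dtype=dtype),
            A_csim=A_csim,
            A_gec=A_gec,
            A_ceg=A_ceg,
            expr_indptr=expr.indptr.astype(np.int64),
            expr_gene_idx=expr.indices.astype(np.int64),
            expr_cell_idx=np.repeat(
                np.arange(n, dtype=np.int64), np.diff(expr.indptr)
            ),
            n_cells=n,
            n_genes=s,
        )


@dataclass
class ForwardResult:
    cell_layers: List[Tensor]     # h^{c(0)} .. h^{c(L)}
    gene_layers: List[Tensor]     # h^{g(0)} .. h^{g(L)}
    attention: Tensor             # per expression edge, cell-major
    logits: Tensor                # N x C
    log_probs: Tensor             # N x C

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_probs.data)

    def attention_csr(self, n_cells: int, n_genes: int, indptr, gene_idx) -> sp.csr_matrix:
        return sp.csr_matrix(
            (self.attention.data, gene_idx, indptr), shape=(n_cells, n_genes)
        )


def forward(gt: GraphTensors, state: ModelState) -> ForwardResult:
    cfg = state.config
    P = state.params
    slope, eps = cfg.leaky_slope, cfg.ln_eps
    X = Tensor(gt.X)

    # layer 0
    h_c = ((X @ P["w_c0"]) + P["b_c0"]).leaky_relu(slope).layer_norm(eps)
    h_g = (
        ((X @ P["w_cg0"]).spmm(gt.A_ceg) + P["b_g0"]).leaky_relu(slope).layer_norm(eps)
    )
    cell_layers, gene_layers = [h_c], [h_g]

    for l in range(1, cfg.n_layers + 1):
        z_c = (
            h_c.spmm(gt.A_csim) @ P[f"w_csim_{l}"]
            + h_g.spmm(gt.A_gec) @ P[f"w_gec_{l}"]
            + (h_c @ P[f"w_cself_{l}"])
            + P[f"b_c_{l}"]
        )
        z_g = (
            h_c.spmm(gt.A_ceg) @ P[f"w_ceg_{l}"]
            + (h_g @ P[f"w_gself_{l}"])
            + P[f"b_g_{l}"]
        )
        h_c = z_c.leaky_relu(slope).layer_norm(eps)
        h_g = z_g.leaky_relu(slope).layer_norm(eps)
        cell_layers.append(h_c)
        gene_layers.append(h_g)

    # attention classifier on expression edges
    C = state.n_classes
    hc_att = h_c @ P["w_att_c"]            # N x C
    hg_att = h_g @ P["w_att_g"]            # s x C
    v_c = P["v"].slice0(0, C)
    v_g = P["v"].slice0(C, 2 * C)
    a_cell = hc_att @ v_c                  # N
    a_gene = hg_att @ v_g                  # s
    e = (
        a_cell.gather(gt.expr_cell_idx) + a_gene.gather(gt.expr_gene_idx)
    ).leaky_relu(slope)
    att = e.segment_softmax(gt.expr_indptr)
    logits = (
        attention_matmul(att, gt.expr_gene_idx, gt.expr_indptr, hg_att, gt.n_genes)
        + P["b_out"]
    )
    log_probs = logits.log_softmax()
    return ForwardResult(cell_layers, gene_layers, att, logits, log_probs)


def class_weights(labels: np.ndarray, classes: List[str]) -> np.ndarray:
    """Per-class weights proportional to 1/sqrt(class size), summing to C."""
    labels = np.asarray(labels, dtype=object)
    counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    if (counts == 0).any():
        empty = [c for c, n in zip(classes, counts) if n == 0]
        raise ValueError(f"classes with no cells: {empty}")
    w = 1.0 / np.sqrt(counts)
    return w * (len(classes) / w.sum())


def classification_loss(
    result: ForwardResult,
    train_idx: np.ndarray,
    label_idx: np.ndarray,
    weights: np.ndarray,
    state: ModelState,
    weight_decay: Optional[float] = None,
    label_smoothing: Optional[float] = None,
) -> Tensor:
    """Weighted, L2-penalized, label-smoothed cross entropy on train cells.

    ``train_idx`` indexes rows of the logits (reference training cells);
    ``label_idx`` gives their class indices.  The L2 penalty covers the
    weight matrices and the attention vector, not the biases.
    """
    cfg = state.config
    lam = cfg.weight_decay if weight_decay is None else weight_decay
    eps = cfg.label_smoothing if label_smoothing is None else label_smoothing
    m = len(train_idx)
    C = state.n_classes
    if m == 0:
        raise ValueError("no training cells")
    if label_idx.min() < 0 or label_idx.max() >= C:
        raise ValueError("label index outside the reference class set")

    logp = result.log_probs
    picked = logp.take2d(np.asarray(train_idx), np.asarray(label_idx))
    w_cells = np.asarray(weights, dtype=logp.data.dtype)[label_idx]
    ce = picked.mul_const(w_cells).sum() * (-1.0 / m)

    loss = ce
    if lam:
        l2 = None
        for name in state.weight_names():
            term = state.params[name].sumsq()
            l2 = term if l2 is None else l2 + term
        loss = loss + l2 * lam

    if eps:
        all_logp = logp.gather(np.asarray(train_idx)).sum()
        if cfg.smoothing_sign == "printed":
            smooth = all_logp * (eps / (C * m))
        elif cfg.smoothing_sign == "standard":
            smooth = all_logp * (-eps / (C * m))
        else:
            raise ValueError(f"unknown smoothing_sign {cfg.smoothing_sign!r}")
        loss = loss * (1.0 - eps) + smooth
    return loss
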