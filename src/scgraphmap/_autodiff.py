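"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the heterogeneous graph network needs are implemented:
dense/sparse matrix products, broadcast bias addition, LeakyReLU, non-affine
layer normalization, segment softmax over edge groups, attention-weighted
sparse aggregation, row log-softmax, and a handful of reductions.  Sparse
aggregation matrices (scipy CSR) are treated as constants of the graph
structure; gradients flow only through dense operands.

Every gradient implemented here is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "backward"]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.requires_grad = bool(requires_grad)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- graph construction helpers ------------------------------------

    @staticmethod
    def _make(data, parents, backward_fn) -> "Tensor":
        out = Tensor(data)
        needs = any(p.requires_grad for p in parents)
        out.requires_grad = needs
        if needs:
            out.parents = tuple(parents)
            out._backward = backward_fn
        return out

    # -- operations ----------------------------------------------------

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out_data = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                if b.data.ndim == 1:  # matrix @ vector
                    a.accumulate(np.multiply.outer(g, b.data))
                else:
                    a.accumulate(g @ b.data.T)
            if b.requires_grad:
                b.accumulate(a.data.T @ g)

        return Tensor._make(out_data, (a, b), bw)

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out_data = a.data + b.data

        def bw(g):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (a, b), bw)

    def __mul__(self, scalar: float) -> "Tensor":
        a = self
        s = float(scalar)
        out_data = a.data * s

        def bw(g):
            if a.requires_grad:
                a.accumulate(g * s)

        return Tensor._make(out_data, (a,), bw)

    __rmul__ = __mul__

    def mul_const(self, const) -> "Tensor":
        """Elementwise product with a non-learnable array (broadcastable)."""
        a = self
        c = np.asarray(const)
        out_data = a.data * c

        def bw(g):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g * c, a.data.shape))

        return Tensor._make(out_data, (a,), bw)

    def leaky_relu(self, slope: float) -> "Tensor":
        a = self
        mask = a.data > 0
        out_data = np.where(mask, a.data, slope * a.data)

        def bw(g):
            if a.requires_grad:
                a.accumulate(np.where(mask, g, slope * g))

        return Tensor._make(out_data, (a,), bw)

    def layer_norm(self, eps: float = 1e-5) -> "Tensor":
        """Per-row standardization without learnable affine parameters."""
        a = self
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv

        def bw(g):
            if a.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gym = (g * y).mean(axis=-1, keepdims=True)
                a.accumulate(inv * (g - gm - y * gym))

        return Tensor._make(y, (a,), bw)

    def spmm(self, S) -> "Tensor":
        """S @ self with S a constant aggregation operator.

        S may be a scipy sparse matrix or a dense ndarray (dense pays off
        for high-density operators such as expression-edge means).
        """
        a = self
        if sp.issparse(S):
            S = S.tocsr()
        out_data = S @ a.data

        def bw(g):
            if a.requires_grad:
                a.accumulate(S.T @ g)

        return Tensor._make(out_data, (a,), bw)

    def gather(self, idx: np.ndarray) -> "Tensor":
        a = self
        out_data = a.data[idx]

        def bw(g):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.add.at(acc, idx, g)
                a.accumulate(acc)

        return Tensor._make(out_data, (a,), bw)

    def take2d(self, rows: np.ndarray, cols: np.ndarray) -> "Tensor":
        a = self
        out_data = a.data[rows, cols]

        def bw(g):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.add.at(acc, (rows, cols), g)
                a.accumulate(acc)

        return Tensor._make(out_data, (a,), bw)

    def segment_softmax(self, indptr: np.ndarray) -> "Tensor":
        """Softmax within contiguous segments of a 1-D score vector.

        ``indptr`` delimits segments CSR-style; scores must already be
        ordered segment-major.  Empty segments are allowed.
        """
        a = self
        e = a.data
        starts = indptr[:-1]
        nonempty = indptr[1:] > starts
        # reduceat on empty segments returns garbage; mask them out
        mx = np.full(len(starts), -np.inf, dtype=e.dtype)
        if e.size:
            red = np.maximum.reduceat(e, np.minimum(starts, e.size - 1))
            mx[nonempty] = red[nonempty]
        seg_id = np.repeat(np.arange(len(starts)), np.diff(indptr))
        shifted = e - mx[seg_id]
        ex = np.exp(shifted)
        denom = np.zeros(len(starts), dtype=e.dtype)
        if e.size:
            red = np.add.reduceat(ex, np.minimum(starts, e.size - 1))
            denom[nonempty] = red[nonempty]
        att = ex / denom[seg_id]

        def bw(g):
            if a.requires_grad:
                dot = np.zeros(len(starts), dtype=e.dtype)
                if e.size:
                    red = np.add.reduceat(att * g, np.minimum(starts, e.size - 1))
                    dot[nonempty] = red[nonempty]
                a.accumulate(att * (g - dot[seg_id]))

        return Tensor._make(att, (a,), bw)

    def log_softmax(self) -> "Tensor":
        a = self
        x = a.data
        mx = x.max(axis=-1, keepdims=True)
        shifted = x - mx
        lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        out_data = shifted - lse

        def bw(g):
            if a.requires_grad:
                soft = np.exp(out_data)
                a.accumulate(g - soft * g.sum(axis=-1, keepdims=True))

        return Tensor._make(out_data, (a,), bw)

    def slice0(self, start: int, stop: int) -> "Tensor":
        """Slice along axis 0 (used to split a concatenated vector)."""
        a = self
        out_data = a.data[start:stop]

        def bw(g):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                acc[start:stop] = g
                a.accumulate(acc)

        return Tensor._make(out_data, (a,), bw)

    def sum(self) -> "Tensor":
        a = self

        def bw(g):
            if a.requires_grad:
                a.accumulate(np.full_like(a.data, g))

        return Tensor._make(a.data.sum(), (a,), bw)

    def sumsq(self) -> "Tensor":
        a = self

        def bw(g):
            if a.requires_grad:
                a.accumulate(2.0 * g * a.data)

        return Tensor._make((a.data * a.data).sum(), (a,), bw)


def attention_matmul(
    att: Tensor,
    gene_idx: np.ndarray,
    indptr: np.ndarray,
    M: Tensor,
    n_genes: int,
) -> Tensor:
    """Per-cell attention-weighted sum of gene rows.

    ``out[i] = sum_e att[e] * M[gene_idx[e]]`` over the edges of cell ``i``
    (edges are cell-major, delimited by ``indptr``).  Implemented as a
    sparse matrix product so the large edge-by-feature intermediate is
    never materialized in the forward pass.
    """
    n_cells = len(indptr) - 1
    A = sp.csr_matrix(
        (att.data, gene_idx, indptr), shape=(n_cells, n_genes)
    )
    out_data = A @ M.data
    cell_idx = np.repeat(np.arange(n_cells), np.diff(indptr))

    def bw(g):
        if M.requires_grad:
            M.accumulate(A.T @ g)
        if att.requires_grad:
            att.accumulate(np.einsum("ij,ij->i", g[cell_idx], M.data[gene_idx]))

    return Tensor._make(out_data, (att, M), bw)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient g to the given operand shape after broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def backward(loss: Tensor) -> None:
    """Run reverse-mode accumulation from a scalar loss node."""
    if loss.data.ndim != 0:
        raise ValueError("backward() requires a scalar loss")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    loss.grad = np.array(1.0, dtype=loss.data.dtype)
    for node in reversed(topo):
        if node._backward is not None:
            node._backward(node.grad)
            node.grad = None  # free intermediate gradients eagerly
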