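"""Full-graph training loop, checkpoint selection, and label transfer.

Training is transductive: every forward pass embeds all cells (reference
and query) on the joint graph, but the loss is evaluated on reference
cells only.  A stratified hold-out share of the reference is scored every
few iterations; the checkpoint with the best smoothed hold-out accuracy
(trailing window of 5 evaluations, ties to the latest) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ._autodiff import backward
from .hetgraph import HeteroGraph
from .nnmodel import (
    ForwardResult,
    GraphTensors,
    ModelState,
    class_weights,
    classification_loss,
    forward,
)


@dataclass
class TrainConfig:
    learning_rate: float = 5e-3
    n_iterations: int = 1000
    seed: int = 0
    checkpoint_every: int = 10
    eval_fraction: float = 0.1
    grad_clip: Optional[float] = None
    checkpoint_strategy: str = "holdout_smoothed"  # or "last"
    # linear learning-rate ramp over the first iterations; Adam's initial
    # near-sign-magnitude steps otherwise swing the wide classifier head
    # hard enough to scramble early training on some realizations
    warmup_iterations: int = 30

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 <= self.eval_fraction < 1):
            raise ValueError("eval_fraction must be in [0, 1)")


@dataclass
class TrainResult:
    state: ModelState
    classes: List[str]
    loss_trace: np.ndarray
    holdout_iters: List[int]
    holdout_scores: List[float]
    selected_iteration: int

    def loss_trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": np.arange(1, len(self.loss_trace) + 1), "loss": self.loss_trace}
        )


@dataclass
class PredictionResult:
    cell_ids: np.ndarray
    classes: List[str]
    probabilities: np.ndarray       # query cells x C
    labels: np.ndarray              # argmax class names
    max_prob: np.ndarray
    unknown: Optional[np.ndarray] = None  # filled by postanalysis

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids.astype(str),
                "predicted_label": self.labels.astype(str),
                "max_probability": self.max_prob,
            }
        )
        if self.unknown is not None:
            df["unknown"] = self.unknown
            df["final_label"] = np.where(
                self.unknown, "unknown", self.labels.astype(str)
            )
        for j, c in enumerate(self.classes):
            df[f"prob_{c}"] = self.probabilities[:, j]
        return df

    def to_tsv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


class Adam:
    """Standard Adam with bias correction over a parameter dict."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(
        self,
        grad_clip: Optional[float] = None,
        decay: Optional[Dict[str, float]] = None,
    ) -> None:
        """One Adam update; ``decay`` maps parameter names to decoupled
        weight-decay coefficients (theta <- theta * (1 - lr * coef))."""
        self.t += 1
        grads = {k: p.grad for k, p in self.params.items()}
        if grad_clip is not None:
            total = np.sqrt(
                sum(float((g * g).sum()) for g in grads.values() if g is not None)
            )
            if total > grad_clip:
                scale = grad_clip / (total + 1e-12)
                grads = {k: (None if g is None else g * scale) for k, g in grads.items()}
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            update = (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
            p.data = p.data - self.lr * update
            if decay and k in decay:
                p.data = p.data * (1.0 - self.lr * decay[k])

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def stratified_holdout(
    labels: np.ndarray, fraction: float, seed: int
) -> np.ndarray:
    """Boolean mask of held-out cells, at least one per class when possible."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    mask = np.zeros(len(labels), dtype=bool)
    if fraction <= 0:
        return mask
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            continue  # keep singletons in training
        n_hold = max(1, int(round(fraction * idx.size)))
        n_hold = min(n_hold, idx.size - 1)
        mask[rng.choice(idx, size=n_hold, replace=False)] = True
    return mask


def train(
    graph: HeteroGraph,
    state: ModelState,
    labels_ref: np.ndarray,
    config: TrainConfig,
    graph_tensors: Optional[GraphTensors] = None,
) -> TrainResult:
    ref_idx = np.flatnonzero(graph.ref_mask)
    labels_ref = np.asarray(labels_ref, dtype=object)
    if len(labels_ref) != len(ref_idx):
        raise ValueError("labels_ref must cover every reference cell")
    classes = sorted(map(str, set(labels_ref)))
    if len(classes) != state.n_classes:
        raise ValueError(
            f"model built for {state.n_classes} classes, labels have {len(classes)}"
        )
    class_to_idx = {c: i for i, c in enumerate(classes)}
    label_idx_all = np.array([class_to_idx[str(l)] for l in labels_ref], dtype=np.int64)

    hold_mask = stratified_holdout(labels_ref, config.eval_fraction, config.seed)
    train_rows = ref_idx[~hold_mask]
    train_lab = label_idx_all[~hold_mask]
    hold_rows = ref_idx[hold_mask]
    hold_lab = label_idx_all[hold_mask]
    weights = class_weights(labels_ref[~hold_mask], classes)

    gt = graph_tensors or GraphTensors.from_graph(graph, dtype=state.config.np_dtype())
    opt = Adam(state.params, lr=config.learning_rate)
    # The L2 complexity penalty is applied as decoupled weight decay on the
    # weight matrices and attention vector; the loss *trace* reports the
    # full penalized objective.
    lam = state.config.weight_decay
    eps_s = state.config.label_smoothing
    decay = {k: lam for k in state.weight_names()} if lam else None

    losses: List[float] = []
    hold_iters: List[int] = []
    hold_scores: List[float] = []
    recent: List[float] = []
    best_smoothed = -np.inf
    best_arrays: Optional[Dict[str, np.ndarray]] = None
    best_iter = config.n_iterations

    use_holdout = (
        config.checkpoint_strategy == "holdout_smoothed" and hold_rows.size > 0
    )

    # clipping is off until instability (a loss spike) is observed
    clip_active = config.grad_clip
    for it in range(1, config.n_iterations + 1):
        opt.zero_grad()
        result = forward(gt, state)
        loss = classification_loss(
            result, train_rows, train_lab, weights, state, weight_decay=0.0
        )
        l2 = sum(
            float((state.params[k].data.astype(np.float64) ** 2).sum())
            for k in state.weight_names()
        )
        value = float(loss.data) + (1.0 - eps_s) * lam * l2
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite training loss at iteration {it}; "
                f"last good iteration {it - 1}"
                + (f" (loss {losses[-1]:.6f})" if losses else "")
            )
        losses.append(value)
        # instability watch on the data-fit part of the loss (the L2 value
        # moves smoothly and would mask any spike)
        ce_value = float(loss.data)
        if (
            clip_active is None
            and it > 1
            and ce_value > 3.0 * max(prev_ce, 0.1)
        ):
            clip_active = 5.0  # global-norm guard for the rest of the run
        prev_ce = ce_value

        if use_holdout and (it % config.checkpoint_every == 0 or it == config.n_iterations):
            pred = result.log_probs.data[hold_rows].argmax(axis=1)
            acc = float((pred == hold_lab).mean())
            hold_iters.append(it)
            hold_scores.append(acc)
            recent.append(acc)
            if len(recent) > 5:
                recent.pop(0)
            smoothed = float(np.mean(recent))
            if smoothed >= best_smoothed:  # >= so ties go to the latest
                best_smoothed = smoothed
                best_arrays = state.copy_arrays()
                best_iter = it

        backward(loss)
        if config.warmup_iterations and it <= config.warmup_iterations:
            opt.lr = config.learning_rate * it / config.warmup_iterations
        else:
            opt.lr = config.learning_rate
        opt.step(grad_clip=clip_active, decay=decay)

    if use_holdout and best_arrays is not None:
        state.load_arrays(best_arrays)
        selected = best_iter
    else:
        selected = config.n_iterations

    return TrainResult(
        state=state,
        classes=classes,
        loss_trace=np.array(losses),
        holdout_iters=hold_iters,
        holdout_scores=hold_scores,
        selected_iteration=selected,
    )


def select_checkpoint(scores: List[float], window: int = 5) -> int:
    """Index of the snapshot maximizing the trailing smoothed score.

    Ties are resolved to the latest snapshot.
    """
    if not scores:
        raise ValueError("no snapshots to select from")
    best, best_i = -np.inf, 0
    for i in range(len(scores)):
        smoothed = float(np.mean(scores[max(0, i - window + 1) : i + 1]))
        if smoothed >= best:
            best, best_i = smoothed, i
    return best_i


def predict(
    state: ModelState,
    graph: HeteroGraph,
    classes: List[str],
    graph_tensors: Optional[GraphTensors] = None,
) -> tuple[PredictionResult, ForwardResult]:
    """Forward pass and per-query-cell class probabilities.

    Pure function of (state, graph): repeated calls are bit-identical.
    Also returns the full forward result so callers can reuse embeddings
    and attention without recomputation.
    """
    if len(classes) != state.n_classes:
        raise ValueError("class list does not match the trained model")
    gt = graph_tensors or GraphTensors.from_graph(graph, dtype=state.config.np_dtype())
    result = forward(gt, state)
    probs = result.probabilities
    q = np.flatnonzero(graph.query_mask)
    qp = probs[q].astype(np.float64)
    qp = qp / qp.sum(axis=1, keepdims=True)
    arg = qp.argmax(axis=1)
    pred = PredictionResult(
        cell_ids=graph.cell_ids[q],
        classes=list(classes),
        probabilities=qp,
        labels=np.array([classes[i] for i in arg], dtype=object),
        max_prob=qp[np.arange(len(q)), arg],
        unknown=None,
    )
    return pred, result
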