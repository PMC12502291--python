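"""Independent reference implementations used only by the tests.

Everything here is written as explicit scalar/loop code straight from the
model's defining equations and the textbook definitions of the metrics,
deliberately avoiding the package's vectorized/sparse code paths.
"""

from __future__ import annotations

import numpy as np


def leaky(x, slope):
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, x, slope * x)


def layer_norm_vec(v, eps=1e-5):
    v = np.asarray(v, dtype=np.float64)
    mu = v.mean()
    var = ((v - mu) ** 2).mean()
    return (v - mu) / np.sqrt(var + eps)


def _receivers(edges, dst):
    """Unique source nodes of edges whose destination is ``dst``."""
    return sorted({int(s) for s, d in edges if int(d) == dst})


def dense_forward(graph, params, n_layers, slope, ln_eps=1e-5):
    """Explicit-loop forward pass over a HeteroGraph.

    ``params`` maps the package's parameter names to float64 arrays with
    weights stored (in_dim, out_dim).  Returns a dict with per-layer
    embeddings, per-edge attention, logits and probabilities.
    """
    X = np.asarray(graph.cell_features, dtype=np.float64)
    n = len(graph.cell_ids)
    s = len(graph.gene_ids)
    ceg = [(int(a), int(b)) for a, b in graph.edges["cell_express_gene"]]
    gec = [(int(a), int(b)) for a, b in graph.edges["gene_expressed_by_cell"]]
    csim = [(int(a), int(b)) for a, b in graph.edges["cell_similar_to_cell"]]

    h_c = np.zeros((n, params["b_c0"].shape[0]))
    for i in range(n):
        h_c[i] = layer_norm_vec(
            leaky(params["w_c0"].T @ X[i] + params["b_c0"], slope), ln_eps
        )
    h_g = np.zeros((s, params["b_g0"].shape[0]))
    for k in range(s):
        cells = _receivers(ceg, k)  # cells expressing gene k
        acc = np.zeros_like(params["b_g0"], dtype=np.float64)
        if cells:
            for i in cells:
                acc += params["w_cg0"].T @ X[i]
            acc /= len(cells)
        h_g[k] = layer_norm_vec(leaky(acc + params["b_g0"], slope), ln_eps)

    cell_layers, gene_layers = [h_c], [h_g]
    for l in range(1, n_layers + 1):
        new_c = np.zeros_like(h_c)
        for i in range(n):
            z = params[f"w_cself_{l}"].T @ h_c[i] + params[f"b_c_{l}"]
            nb = _receivers(csim, i)
            if nb:
                z += np.mean([params[f"w_csim_{l}"].T @ h_c[j] for j in nb], axis=0)
            ng = _receivers(gec, i)  # genes expressed by cell i
            if ng:
                z += np.mean([params[f"w_gec_{l}"].T @ h_g[k] for k in ng], axis=0)
            new_c[i] = layer_norm_vec(leaky(z, slope), ln_eps)
        new_g = np.zeros_like(h_g)
        for k in range(s):
            z = params[f"w_gself_{l}"].T @ h_g[k] + params[f"b_g_{l}"]
            nc = _receivers(ceg, k)
            if nc:
                z += np.mean([params[f"w_ceg_{l}"].T @ h_c[i] for i in nc], axis=0)
            new_g[k] = layer_norm_vec(leaky(z, slope), ln_eps)
        h_c, h_g = new_c, new_g
        cell_layers.append(h_c)
        gene_layers.append(h_g)

    C = params["b_out"].shape[0]
    v = params["v"]
    att = {}
    logits = np.zeros((n, C))
    for i in range(n):
        genes = _receivers(gec, i)
        scores = []
        for j in genes:
            concat = np.concatenate(
                [params["w_att_c"].T @ h_c[i], params["w_att_g"].T @ h_g[j]]
            )
            scores.append(leaky(float(v @ concat), slope))
        scores = np.array(scores, dtype=np.float64)
        ex = np.exp(scores - scores.max())
        weights = ex / ex.sum()
        out = np.zeros(C)
        for w, j in zip(weights, genes):
            att[(i, j)] = w
            out += w * (params["w_att_g"].T @ h_g[j])
        logits[i] = out + params["b_out"]
    probs = np.zeros_like(logits)
    for i in range(n):
        ex = np.exp(logits[i] - logits[i].max())
        probs[i] = ex / ex.sum()
    return {
        "cell_layers": cell_layers,
        "gene_layers": gene_layers,
        "attention": att,
        "logits": logits,
        "probs": probs,
    }


def dense_loss(
    probs, train_idx, label_idx, weights, params, lam, eps, smoothing_sign="standard"
):
    """Scalar-loop evaluation of the penalized, smoothed training loss."""
    m = len(train_idx)
    C = probs.shape[1]
    ce = 0.0
    for i, y in zip(train_idx, label_idx):
        p = max(float(probs[i, y]), 1e-300)
        ce += weights[y] * np.log(p)
    ce = -ce / m
    l2 = 0.0
    for name, arr in params.items():
        if name.startswith("w_") or name == "v":
            l2 += float((np.asarray(arr, dtype=np.float64) ** 2).sum())
    l1 = ce + lam * l2
    smooth = 0.0
    for i in train_idx:
        for j in range(C):
            smooth += np.log(max(float(probs[i, j]), 1e-300))
    if smoothing_sign == "standard":
        smooth = -smooth
    return (1 - eps) * l1 + (eps / (C * m)) * smooth


def metrics_loop(true_labels, pred_labels):
    """Confusion-matrix accuracy / macro F1 / weighted F1 by scalar loops."""
    true_labels = [str(x) for x in true_labels]
    pred_labels = [str(x) for x in pred_labels]
    classes = sorted(set(true_labels) | set(pred_labels))
    n = len(true_labels)
    correct = sum(1 for t, p in zip(true_labels, pred_labels) if t == p)
    accuracy = correct / n
    f1s, supports = [], []
    for c in classes:
        tp = sum(1 for t, p in zip(true_labels, pred_labels) if t == c and p == c)
        fp = sum(1 for t, p in zip(true_labels, pred_labels) if t != c and p == c)
        fn = sum(1 for t, p in zip(true_labels, pred_labels) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        f1s.append(f1)
        supports.append(sum(1 for t in true_labels if t == c))
    macro = sum(f1s) / len(classes)
    weighted = sum(f * s for f, s in zip(f1s, supports)) / n
    return accuracy, macro, weighted


def degs_loop(X, gene_ids, groups, n_top=50, alpha=0.05):
    """One-vs-rest Welch t-test DEG ranking via per-gene scalar loops."""
    import scipy.stats

    X = np.asarray(X, dtype=np.float64)
    groups = np.asarray(groups, dtype=object)
    out = {}
    for g in sorted(set(map(str, groups))):
        mask = np.array([str(x) == g for x in groups])
        stats = []
        for j in range(X.shape[1]):
            t, p = scipy.stats.ttest_ind(X[mask, j], X[~mask, j], equal_var=False)
            if np.isnan(p):
                t, p = 0.0, 1.0
            stats.append((t, p))
        pvals = np.array([p for _, p in stats])
        # Benjamini-Hochberg, step-up, by hand
        order = np.argsort(pvals, kind="stable")
        q = np.empty_like(pvals)
        prev = 1.0
        for rank_pos in range(len(pvals) - 1, -1, -1):
            j = order[rank_pos]
            val = pvals[j] * len(pvals) / (rank_pos + 1)
            prev = min(prev, val)
            q[j] = prev
        keep = [j for j in range(X.shape[1]) if q[j] < alpha]
        keep.sort(key=lambda j: (q[j], -abs(stats[j][0]), str(gene_ids[j])))
        out[g] = [str(gene_ids[j]) for j in keep[:n_top]]
    return out
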