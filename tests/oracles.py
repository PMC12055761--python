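"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities with the slowest, most transparent
algorithm available (explicit loops, pairwise counting, step-wise
integration) so they share no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def auc_pairwise(scores, labels) -> float:
    """AUC as the fraction of concordant positive-negative pairs (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_stepwise(scores, labels) -> float:
    """Area under precision-recall by step-wise (rectangle) integration.

    Sweeps the unique score values in decreasing order as thresholds and sums
    precision * (recall increment) — the non-interpolated definition.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    area = 0.0
    prev_recall = 0.0
    for threshold in sorted(set(scores), reverse=True):
        predicted = scores >= threshold
        tp = int(((labels == 1) & predicted).sum())
        fp = int(((labels == 0) & predicted).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


def gin_layer_oracle(
    H: np.ndarray,
    biadjacency: np.ndarray,
    eps: float,
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """One GIN layer by explicit per-node loops over a bipartite graph.

    ``H`` stacks metabolite rows then disease rows; messages flow only along
    ``biadjacency``.  The layer transform is Linear -> ReLU -> Linear.
    """
    U, V = biadjacency.shape
    out = np.zeros((U + V, W2.shape[1]))
    for node in range(U + V):
        agg = (1.0 + eps) * H[node].astype(float).copy()
        if node < U:
            for j in range(V):
                if biadjacency[node, j]:
                    agg = agg + H[U + j]
        else:
            for i in range(U):
                if biadjacency[i, node - U]:
                    agg = agg + H[i]
        hidden = np.maximum(agg @ W1 + b1, 0.0)
        out[node] = hidden @ W2 + b2
    return out


def gin_encode_oracle(X, biadjacency, model) -> np.ndarray:
    """Full GIN encoder forward pass via :func:`gin_layer_oracle`."""
    H = np.asarray(X, dtype=float)
    for layer in model.encoder_layers:
        (W1, b1), (W2, b2) = layer["mlp"]
        H = gin_layer_oracle(
            H,
            biadjacency,
            float(layer["eps"].value),
            W1.value,
            b1.value,
            W2.value,
            b2.value,
        )
    return H
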