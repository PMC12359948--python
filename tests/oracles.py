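"""Independent brute-force oracles for the message-passing layer equations.

These are deliberately written as dense-matrix / per-node loop evaluations,
sharing no code with the vectorised implementations they check.
"""

import numpy as np


def dense_gcn(H, adj, W):
    n = H.shape[0]
    ahat = adj + np.eye(n)
    dhat = ahat.sum(axis=1)
    dinv = np.diag(1.0 / np.sqrt(dhat))
    return dinv @ ahat @ dinv @ H @ W.T


def loop_gat(H, adj, W, a, slope=0.2):
    n = H.shape[0]
    hw = H @ W.T
    out = np.zeros((n, W.shape[0]))
    alphas = {}
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j]] + [i]
        logits = []
        for j in neigh:
            s = a @ np.concatenate([hw[i], hw[j]])
            logits.append(s if s > 0 else slope * s)
        logits = np.array(logits)
        e = np.exp(logits - logits.max())
        alpha = e / e.sum()
        for j, al in zip(neigh, alpha):
            alphas[(i, j)] = al
        out[i] = sum(al * hw[j] for j, al in zip(neigh, alpha))
    return out, alphas


def loop_sage(H, adj, W1, W2):
    n = H.shape[0]
    out = np.zeros((n, W1.shape[0]))
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j]]
        mean = np.mean([H[j] for j in neigh], axis=0) if neigh else np.zeros(H.shape[1])
        out[i] = W1 @ H[i] + W2 @ mean
    return out


def loop_gin(H, adj, W1, b1, W2, b2, eps=0.0):
    n = H.shape[0]
    out = np.zeros((n, W2.shape[0]))
    for i in range(n):
        agg = (1.0 + eps) * H[i] + sum(
            (H[j] for j in range(n) if adj[i, j]), np.zeros(H.shape[1])
        )
        hidden = np.maximum(W1 @ agg + b1, 0.0)
        out[i] = W2 @ hidden + b2
    return out
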