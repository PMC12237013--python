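"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain loops over dense arrays, deliberately
ignoring the package's vectorized/sparse code paths, so the two routes
stay independent.
"""

from __future__ import annotations

import numpy as np


def _act(name):
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    if name == "linear":
        return lambda x: x
    raise ValueError(name)


def _leaky(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def sage_oracle(H, edges, params, activation="relu"):
    n = H.shape[0]
    W_self, W_neigh, b = params["W_self"], params["W_neigh"], params["b"]
    out = np.zeros((n, W_self.shape[1]))
    for v in range(n):
        neigh = [u for (u, t) in edges if t == v]
        mean = (np.mean([H[u] for u in neigh], axis=0) if neigh
                else np.zeros(H.shape[1]))
        out[v] = H[v] @ W_self + mean @ W_neigh + b[0]
    return _act(activation)(out)


def gcn_oracle(H, edges, params, activation="relu"):
    n = H.shape[0]
    W, b = params["W"], params["b"]
    arcs = list(edges) + [(v, v) for v in range(n)]
    in_deg = np.zeros(n)
    for (u, v) in edges:
        in_deg[v] += 1
    d_hat = in_deg + 1
    out = np.zeros((n, W.shape[1]))
    for (u, v) in arcs:
        out[v] += (H[u] @ W) / np.sqrt(d_hat[u] * d_hat[v])
    return _act(activation)(out + b[0])


def gin_oracle(H, edges, params, activation="relu", eps=0.0):
    n = H.shape[0]
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]
    agg = np.zeros_like(H)
    for (u, v) in edges:
        agg[v] += H[u]
    z = (1 + eps) * H + agg
    return _act(activation)(np.maximum(z @ W1 + b1[0], 0.0) @ W2 + b2[0])


def gat_oracle(H, edges, params, n_heads=1, variant="v1", combine="concat",
               activation="relu", slope=0.2):
    n = H.shape[0]
    arcs = list(edges) + [(v, v) for v in range(n)]
    heads = []
    for h in range(n_heads):
        if variant == "v1":
            W = params[f"W{h}"]
            a_src, a_dst = params[f"a_src{h}"][:, 0], params[f"a_dst{h}"][:, 0]
            Wh = H @ W
            scores = {(u, v): _leaky(Wh[u] @ a_src + Wh[v] @ a_dst, slope)
                      for (u, v) in arcs}
            msg = Wh
        else:
            Ws, Wd, a = params[f"W_src{h}"], params[f"W_dst{h}"], \
                params[f"a{h}"][:, 0]
            Zs, Zd = H @ Ws, H @ Wd
            scores = {(u, v): _leaky(Zs[u] + Zd[v], slope) @ a
                      for (u, v) in arcs}
            msg = Zs
        out = np.zeros((n, msg.shape[1]))
        for v in range(n):
            inc = [(u, vv) for (u, vv) in arcs if vv == v]
            s = np.array([scores[a_] for a_ in inc])
            alpha = np.exp(s - s.max())
            alpha /= alpha.sum()
            for (u, _), al in zip(inc, alpha):
                out[v] += al * msg[u]
        heads.append(out)
    combined = (np.concatenate(heads, axis=1) if combine == "concat"
                else np.mean(heads, axis=0))
    return _act(activation)(combined + params["b"][0])


LAYER_ORACLES = {"sage": sage_oracle, "gcn": gcn_oracle, "gin": gin_oracle}


def layer_oracle(layer_type, H, edges, layer):
    """Dispatch on layer type using the layer's own parameter arrays."""
    params = {k: v.data for k, v in layer.params.items()}
    if layer_type in LAYER_ORACLES:
        return LAYER_ORACLES[layer_type](H, edges, params,
                                         activation=layer.activation)
    variant = "v1" if layer_type == "gat" else "v2"
    return gat_oracle(H, edges, params, n_heads=layer.n_heads,
                      variant=variant, combine=layer.combine,
                      activation=layer.activation, slope=layer.slope)


def auroc_pairwise(labels, scores):
    """Exhaustive positive-negative pair comparison, ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def confusion_metrics(labels, predictions):
    """F1-macro and MCC straight from the confusion-matrix formulas."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))

    def f1(tp_, fp_, fn_):
        denom = 2 * tp_ + fp_ + fn_
        return 2 * tp_ / denom if denom else 0.0

    f1_pos = f1(tp, fp, fn)
    f1_neg = f1(tn, fn, fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc_val = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom else 0.0
    return (f1_pos + f1_neg) / 2.0, mcc_val


def knn_neighbors(X, k):
    """O(N^2) nearest-neighbour sets with index tie-break."""
    n = X.shape[0]
    out = []
    for v in range(n):
        d = [(float(np.sum((X[v] - X[u]) ** 2)), u)
             for u in range(n) if u != v]
        d.sort()
        out.append([u for _, u in d[:k]])
    return out


def average_linkage(X):
    """O(n^3) agglomerative average-linkage clustering (Euclidean).

    Returns merge rows (idx_a, idx_b, height, size) in scipy's linkage
    convention (lowest-index pair on ties).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(X[i] - X[j]))

    def d(a, b):
        total = 0.0
        for i in clusters[a]:
            for j in clusters[b]:
                key = (min(i, j), max(i, j))
                total += np.sqrt(np.sum((X[i] - X[j]) ** 2))
        return total / (len(clusters[a]) * len(clusters[b]))

    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                h = d(a, b)
                if best is None or h < best[0] - 1e-12:
                    best = (h, a, b)
        h, a, b = best
        merges.append((a, b, h, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(merges)
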