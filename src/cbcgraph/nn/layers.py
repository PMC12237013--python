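"""Message-passing layers implemented from their defining update rules.

All layers map an (N, F_in) node-feature matrix and a directed edge list to
an (N, F_out) matrix. Messages flow along arcs ``source -> target``:

* ``sage``  — GraphSAGE with mean aggregation:
  ``h'_v = act(W_self h_v + W_neigh mean_{u->v} h_u + b)``; an empty
  in-neighbourhood contributes a zero vector.
* ``gcn``   — symmetrically normalized convolution with mandatory
  self-loops: ``h'_v = act(sum_u W h_u / sqrt(d_u d_v) + b)`` with
  ``d = in_degree + 1``.
* ``gat`` / ``gatv2`` — attention-weighted mean over the in-neighbourhood
  (self-loop included). GAT scores ``leaky_relu(a_s . W h_u + a_t . W h_v)``;
  GATv2 applies the leaky-ReLU before the attention vector,
  ``a . leaky_relu(W_s h_u + W_t h_v)``, which makes the attention strictly
  more expressive. Heads are concatenated in hidden layers and averaged at
  the output layer.
* ``gin``   — Graph Isomorphism Network: ``h'_v = MLP((1+eps) h_v +
  sum_{u->v} h_u)`` with a two-layer MLP and ``eps = 0``.

``mlp`` is a dense layer that ignores the edge list; it backs the tabular
neural-network baseline so that it shares the exact training loop of the
graph models.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["EdgeCache", "make_layer", "SAGELayer", "GCNLayer", "GATLayer",
           "GINLayer", "DenseLayer", "LAYER_TYPES"]

LAYER_TYPES = ("sage", "gcn", "gat", "gatv2", "gin", "mlp")


def _gather_matrix(idx: np.ndarray, n: int):
    """CSR matrix G with G[i, idx[i]] = 1: ``G @ H`` gathers rows,
    ``G.T @ M`` scatter-adds (segment-sums) rows."""
    e = len(idx)
    return sparse.csr_matrix(
        (np.ones(e), (np.arange(e), idx)), shape=(e, n))


class EdgeCache:
    """Precomputed edge indexing for one graph.

    ``src``/``tgt`` are the raw arcs; ``src_sl``/``tgt_sl`` append one
    self-loop per node (in node order, after the raw arcs). ``in_deg`` is
    the raw in-degree. ``G_*`` are CSR gather matrices whose transposes
    segment-sum; layers use them through :func:`autodiff.spmm` so the
    hot path is sparse matrix algebra rather than indexed scatters.
    """

    def __init__(self, edges: np.ndarray, n_nodes: int):
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        self.n = int(n_nodes)
        self.src = edges[:, 0]
        self.tgt = edges[:, 1]
        self.in_deg = np.bincount(self.tgt, minlength=self.n)
        loop = np.arange(self.n, dtype=np.int64)
        self.src_sl = np.concatenate([self.src, loop])
        self.tgt_sl = np.concatenate([self.tgt, loop])
        # GCN symmetric normalization with d_hat = in-degree + 1
        d_hat = (self.in_deg + 1).astype(np.float64)
        self.gcn_coef = 1.0 / np.sqrt(d_hat[self.src_sl] * d_hat[self.tgt_sl])
        # mean-aggregation denominator (0-degree nodes divide by 1)
        self.mean_den = np.maximum(self.in_deg, 1).astype(np.float64)[:, None]
        self.G_src = _gather_matrix(self.src, self.n)
        self.S_tgt = _gather_matrix(self.tgt, self.n).T.tocsr()
        self.G_src_sl = _gather_matrix(self.src_sl, self.n)
        self.G_tgt_sl = _gather_matrix(self.tgt_sl, self.n)
        self.S_tgt_sl = self.G_tgt_sl.T.tocsr()
        # folded node-to-node operators: one sparse product per aggregation
        self.A_sum = (self.S_tgt @ self.G_src).tocsr()
        self.A_mean = sparse.diags(1.0 / self.mean_den[:, 0]) @ self.A_sum
        self.A_gcn = (self.S_tgt_sl @ sparse.diags(self.gcn_coef)
                      @ self.G_src_sl).tocsr()


def _glorot(rng, f_in, f_out):
    s = np.sqrt(6.0 / (f_in + f_out))
    return rng.uniform(-s, s, size=(f_in, f_out))


def _act(name):
    if name == "relu":
        return ad.relu
    if name == "linear":
        return lambda t: t
    if name == "leaky_relu":
        return ad.leaky_relu
    raise ValueError(f"unknown activation {name!r}")


class _Layer:
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=np.float64)


class DenseLayer(_Layer):
    """Edge-agnostic dense layer (the tabular MLP building block)."""

    def __init__(self, f_in, f_out, activation="relu", rng=None):
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.params = {
            "W": Tensor(_glorot(rng, f_in, f_out), requires_grad=True),
            "b": Tensor(np.zeros((1, f_out)), requires_grad=True),
        }

    def forward(self, H: Tensor, cache: EdgeCache) -> Tensor:
        return _act(self.activation)(H @ self.params["W"] + self.params["b"])


class SAGELayer(_Layer):
    def __init__(self, f_in, f_out, activation="relu", rng=None):
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.params = {
            "W_self": Tensor(_glorot(rng, f_in, f_out), requires_grad=True),
            "W_neigh": Tensor(_glorot(rng, f_in, f_out), requires_grad=True),
            "b": Tensor(np.zeros((1, f_out)), requires_grad=True),
        }

    def forward(self, H: Tensor, cache: EdgeCache) -> Tensor:
        mean = ad.spmm(cache.A_mean, H)
        out = H @ self.params["W_self"] + mean @ self.params["W_neigh"] \
            + self.params["b"]
        return _act(self.activation)(out)


class GCNLayer(_Layer):
    def __init__(self, f_in, f_out, activation="relu", rng=None):
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.params = {
            "W": Tensor(_glorot(rng, f_in, f_out), requires_grad=True),
            "b": Tensor(np.zeros((1, f_out)), requires_grad=True),
        }

    def forward(self, H: Tensor, cache: EdgeCache) -> Tensor:
        HW = H @ self.params["W"]
        agg = ad.spmm(cache.A_gcn, HW)
        return _act(self.activation)(agg + self.params["b"])


class GINLayer(_Layer):
    """Sum aggregation followed by a two-layer MLP; eps fixed at 0."""

    def __init__(self, f_in, f_out, activation="relu", rng=None, eps=0.0):
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.eps = float(eps)
        self.params = {
            "W1": Tensor(_glorot(rng, f_in, f_out), requires_grad=True),
            "b1": Tensor(np.zeros((1, f_out)), requires_grad=True),
            "W2": Tensor(_glorot(rng, f_out, f_out), requires_grad=True),
            "b2": Tensor(np.zeros((1, f_out)), requires_grad=True),
        }

    def forward(self, H: Tensor, cache: EdgeCache) -> Tensor:
        agg = ad.spmm(cache.A_sum, H)
        z = H * (1.0 + self.eps) + agg
        hidden = ad.relu(z @ self.params["W1"] + self.params["b1"])
        return _act(self.activation)(
            hidden @ self.params["W2"] + self.params["b2"])


class GATLayer(_Layer):
    """Graph attention layer (v1 or v2) with mandatory self-loops.

    ``combine='concat'`` concatenates heads (hidden layers; ``f_out`` must
    be divisible by ``n_heads``); ``combine='mean'`` averages full-width
    heads (output layer). After a forward pass ``last_attention_`` holds,
    per head, the attention coefficients aligned with
    ``(cache.src_sl, cache.tgt_sl)``.
    """

    def __init__(self, f_in, f_out, activation="relu", rng=None,
                 variant="v1", n_heads=1, combine="concat", slope=0.2):
        rng = rng or np.random.default_rng(0)
        if variant not in ("v1", "v2"):
            raise ValueError(f"unknown GAT variant {variant!r}")
        if combine == "concat" and f_out % n_heads:
            raise ValueError("n_heads must divide f_out when concatenating")
        self.activation = activation
        self.variant = variant
        self.n_heads = int(n_heads)
        self.combine = combine
        self.slope = slope
        self.head_dim = f_out // n_heads if combine == "concat" else f_out
        self.params = {}
        for h in range(self.n_heads):
            if variant == "v1":
                self.params[f"W{h}"] = Tensor(
                    _glorot(rng, f_in, self.head_dim), requires_grad=True)
                self.params[f"a_src{h}"] = Tensor(
                    _glorot(rng, self.head_dim, 1), requires_grad=True)
                self.params[f"a_dst{h}"] = Tensor(
                    _glorot(rng, self.head_dim, 1), requires_grad=True)
            else:
                self.params[f"W_src{h}"] = Tensor(
                    _glorot(rng, f_in, self.head_dim), requires_grad=True)
                self.params[f"W_dst{h}"] = Tensor(
                    _glorot(rng, f_in, self.head_dim), requires_grad=True)
                self.params[f"a{h}"] = Tensor(
                    _glorot(rng, self.head_dim, 1), requires_grad=True)
        self.params["b"] = Tensor(
            np.zeros((1, f_out)), requires_grad=True)
        self.last_attention_: list[np.ndarray] | None = None

    def forward(self, H: Tensor, cache: EdgeCache) -> Tensor:
        heads = []
        self.last_attention_ = []
        for h in range(self.n_heads):
            if self.variant == "v1":
                Wh = H @ self.params[f"W{h}"]
                s_src = ad.reshape(Wh @ self.params[f"a_src{h}"], (-1,))
                s_dst = ad.reshape(Wh @ self.params[f"a_dst{h}"], (-1,))
                scores = ad.leaky_relu(
                    ad.spmm(cache.G_src_sl, s_src)
                    + ad.spmm(cache.G_tgt_sl, s_dst), self.slope)
                msgs = ad.spmm(cache.G_src_sl, Wh)
            else:
                Z_src = H @ self.params[f"W_src{h}"]
                Z_dst = H @ self.params[f"W_dst{h}"]
                pre = ad.leaky_relu(
                    ad.spmm(cache.G_src_sl, Z_src)
                    + ad.spmm(cache.G_tgt_sl, Z_dst), self.slope)
                scores = ad.reshape(pre @ self.params[f"a{h}"], (-1,))
                msgs = ad.spmm(cache.G_src_sl, Z_src)
            alpha = ad.segment_softmax(scores, cache.tgt_sl, cache.n,
                                        scatter=cache.S_tgt_sl)
            self.last_attention_.append(alpha.data.copy())
            agg = ad.spmm(cache.S_tgt_sl, msgs * ad.reshape(alpha, (-1, 1)))
            heads.append(agg)
        if self.combine == "concat":
            out = heads[0] if len(heads) == 1 else ad.concat(heads, axis=1)
        else:
            out = heads[0]
            for extra in heads[1:]:
                out = out + extra
            out = out * (1.0 / len(heads))
        return _act(self.activation)(out + self.params["b"])


def make_layer(layer_type: str, f_in: int, f_out: int, activation: str,
               rng, n_heads: int = 1, combine: str = "concat"):
    if layer_type == "sage":
        return SAGELayer(f_in, f_out, activation, rng)
    if layer_type == "gcn":
        return GCNLayer(f_in, f_out, activation, rng)
    if layer_type == "gin":
        return GINLayer(f_in, f_out, activation, rng)
    if layer_type == "gat":
        return GATLayer(f_in, f_out, activation, rng, variant="v1",
                        n_heads=n_heads, combine=combine)
    if layer_type == "gatv2":
        return GATLayer(f_in, f_out, activation, rng, variant="v2",
                        n_heads=n_heads, combine=combine)
    if layer_type == "mlp":
        return DenseLayer(f_in, f_out, activation, rng)
    raise ValueError(f"unknown layer type {layer_type!r}")
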