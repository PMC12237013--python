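"""Typed message passing on the heterogeneous similarity graph.

Node types are ``measurement`` plus one type per blood parameter (the
percentile-bin nodes). A hetero layer keeps one self-transform per node
type and one message transform per relation; incoming relations of a type
are aggregated independently and summed:

``h'_t(v) = act( W_self_t h(v) + b_t + sum_rel W_rel agg_{u -> v} h(u) )``

with mean aggregation for the SAGE variant. The GIN variant uses sum
aggregation and feeds the combined representation through a per-type
two-layer MLP, the typed generalisation of the isomorphism-network update.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from . import autodiff as ad
from .autodiff import Tensor
from .layers import _Layer, _act, _glorot

__all__ = ["HeteroLayer", "HeteroEdgeCache"]


class HeteroEdgeCache:
    """Edge indexing for a heterogeneous graph.

    ``relations`` maps ``(src_type, dst_type)`` to ``(src_idx, tgt_idx,
    mean_den)`` where ``mean_den`` is the per-destination in-degree
    denominator of that relation (floored at 1).
    """

    def __init__(self, edges: dict, n_by_type: dict[str, int]):
        self.n_by_type = dict(n_by_type)
        self.relations = {}
        for (s, t), e in edges.items():
            e = np.asarray(e, dtype=np.int64).reshape(-1, 2)
            deg = np.bincount(e[:, 1], minlength=n_by_type[t])
            den = np.maximum(deg, 1).astype(np.float64)
            ne = len(e)
            gather = sparse.csr_matrix(
                (np.ones(ne), (np.arange(ne), e[:, 0])),
                shape=(ne, n_by_type[s]))
            scatter = sparse.csr_matrix(
                (np.ones(ne), (e[:, 1], np.arange(ne))),
                shape=(n_by_type[t], ne))
            # folded source-to-destination operators (sum and mean)
            A_sum = (scatter @ gather).tocsr()
            A_mean = sparse.diags(1.0 / den) @ A_sum
            self.relations[(s, t)] = (A_sum, A_mean)


class HeteroLayer(_Layer):
    def __init__(self, f_in_by_type: dict[str, int], f_out: int,
                 activation="relu", rng=None, aggregation: str = "mean"):
        rng = rng or np.random.default_rng(0)
        if aggregation not in ("mean", "sum_mlp"):
            raise ValueError(f"unknown aggregation {aggregation!r}")
        self.activation = activation
        self.aggregation = aggregation
        self.types = list(f_in_by_type)
        self.f_out = int(f_out)
        self.params = {}
        for t, f_in in f_in_by_type.items():
            self.params[f"W_self::{t}"] = Tensor(
                _glorot(rng, f_in, f_out), requires_grad=True)
            self.params[f"b::{t}"] = Tensor(
                np.zeros((1, f_out)), requires_grad=True)
            if aggregation == "sum_mlp":
                self.params[f"W_mlp::{t}"] = Tensor(
                    _glorot(rng, f_out, f_out), requires_grad=True)
                self.params[f"b_mlp::{t}"] = Tensor(
                    np.zeros((1, f_out)), requires_grad=True)
        # relation weights are materialized against the cache on first use
        self._f_in_by_type = dict(f_in_by_type)
        self._rng = rng

    def ensure_relations(self, cache: HeteroEdgeCache) -> None:
        for (s, t) in cache.relations:
            key = f"W_rel::{s}->{t}"
            if key not in self.params:
                self.params[key] = Tensor(
                    _glorot(self._rng, self._f_in_by_type[s], self.f_out),
                    requires_grad=True)

    def forward(self, H_by_type: dict[str, Tensor],
                cache: HeteroEdgeCache) -> dict[str, Tensor]:
        self.ensure_relations(cache)
        out = {}
        for t in self.types:
            z = H_by_type[t] @ self.params[f"W_self::{t}"] \
                + self.params[f"b::{t}"]
            for (s, d), (A_sum, A_mean) in cache.relations.items():
                if d != t:
                    continue
                A = A_mean if self.aggregation == "mean" else A_sum
                agg = ad.spmm(A, H_by_type[s])
                z = z + agg @ self.params[f"W_rel::{s}->{d}"]
            if self.aggregation == "sum_mlp":
                z = ad.relu(z)
                z = z @ self.params[f"W_mlp::{t}"] + self.params[f"b_mlp::{t}"]
            out[t] = _act(self.activation)(z)
        return out
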