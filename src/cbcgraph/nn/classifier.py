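"""Two-layer message-passing node classifier with early stopping.

:class:`GraphNodeClassifier` is a scikit-learn-style estimator over
:class:`~cbcgraph.graphs.Graph` or :class:`~cbcgraph.graphs.HeteroGraph`
objects. Training minimizes cross-entropy on the train-masked nodes with
Adam (learning rate 3e-4 by default) and stops when the validation loss
has increased for ``patience`` consecutive epochs; parameters from the
best-validation-loss epoch are restored. Test masks are never read during
training.

The defaults mirror the training protocol used throughout the package's
experiments: two layers, 128 hidden units, up to 10,000 epochs with
patience 10 for similarity graphs and 5 for patient-centric graphs, and
patient-complete mini-batches of at most 50,000 nodes (full-graph training
whenever the graph is smaller, which it is at desk scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ..graphs import Graph, HeteroGraph
from . import autodiff as ad
from .autodiff import Adam, Tensor
from .hetero import HeteroEdgeCache, HeteroLayer
from .layers import EdgeCache, GATLayer, make_layer

__all__ = ["ModelSpec", "TrainSpec", "GraphNodeClassifier",
           "train_node_classifier", "predict_proba", "extract_attention"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of the node classifier."""

    layer_type: str = "sage"
    n_layers: int = 2
    hidden_dim: int = 128
    n_heads: int = 1
    activation: str = "relu"

    def __post_init__(self):
        if self.hidden_dim < 1 or self.n_heads < 1 or self.n_layers < 1:
            raise ValueError("hidden_dim, n_heads and n_layers must be >= 1")


@dataclass(frozen=True)
class TrainSpec:
    """Optimization protocol."""

    learning_rate: float = 3e-4
    max_epochs: int = 10_000
    patience: int = 10
    batch_size: int = 50_000
    seed: int = 0
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class GraphNodeClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style graph node classifier.

    Parameters mirror :class:`ModelSpec` and :class:`TrainSpec`. ``fit``
    takes a graph whose masks contain non-empty ``train`` and
    ``validation`` entries; ``predict_proba`` returns per-node class
    probabilities (rows sum to 1). ``layer_type='mlp'`` ignores edges and
    yields the tabular neural-network baseline under the identical
    training protocol.
    """

    def __init__(self, layer_type="sage", n_layers=2, hidden_dim=128,
                 n_heads=1, activation="relu", learning_rate=3e-4,
                 max_epochs=10_000, patience=10, batch_size=50_000,
                 class_weight=None, random_state=0):
        self.layer_type = layer_type
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.n_heads = n_heads
        self.activation = activation
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _build_layers(self, graph, rng):
        hetero = isinstance(graph, HeteroGraph)
        if hetero and self.layer_type not in ("sage", "gin"):
            raise ValueError(
                f"layer_type {self.layer_type!r} not supported on "
                "heterogeneous graphs (use 'sage' or 'gin')")
        dims = ([graph.node_features.shape[1]]
                + [self.hidden_dim] * (self.n_layers - 1) + [2])
        layers = []
        for i in range(self.n_layers):
            last = i == self.n_layers - 1
            act = "linear" if last else self.activation
            if hetero:
                if i == 0:
                    f_in = {"measurement": dims[0]}
                    for p, bf in graph.bin_features.items():
                        f_in[p] = bf.shape[1]
                else:
                    f_in = {t: dims[i] for t in
                            ["measurement", *graph.bin_features]}
                layers.append(HeteroLayer(
                    f_in, dims[i + 1], activation=act, rng=rng,
                    aggregation="mean" if self.layer_type == "sage"
                    else "sum_mlp"))
            else:
                layers.append(make_layer(
                    self.layer_type, dims[i], dims[i + 1], act, rng,
                    n_heads=self.n_heads,
                    combine="mean" if last else "concat"))
        return layers

    @staticmethod
    def _cache(graph):
        if isinstance(graph, HeteroGraph):
            n_by_type = {"measurement": graph.n_nodes}
            for p, bf in graph.bin_features.items():
                n_by_type[p] = bf.shape[0]
            return HeteroEdgeCache(graph.edges, n_by_type)
        return EdgeCache(graph.edges, graph.n_nodes)

    def _logits(self, graph, cache) -> Tensor:
        if isinstance(graph, HeteroGraph):
            H = {"measurement": Tensor(graph.node_features)}
            for p, bf in graph.bin_features.items():
                H[p] = Tensor(bf)
            for layer in self.layers_:
                H = layer.forward(H, cache)
            return H["measurement"]
        H = Tensor(graph.node_features)
        for layer in self.layers_:
            H = layer.forward(H, cache)
        return H

    # -- training ----------------------------------------------------------

    def fit(self, graph, y=None):
        masks = graph.masks
        if "train" not in masks or "validation" not in masks:
            raise ValueError("graph masks must include 'train' and 'validation'")
        train_mask, val_mask = masks["train"], masks["validation"]
        labels = graph.labels
        if len(np.unique(labels[train_mask])) < 2:
            raise ValueError("training mask must contain both classes")

        rng = np.random.default_rng(self.random_state)
        self.layers_ = self._build_layers(graph, rng)
        cache = self._cache(graph)
        if isinstance(graph, HeteroGraph):
            for layer in self.layers_:
                layer.ensure_relations(cache)
        params = [p for layer in self.layers_ for p in layer.parameters()]
        opt = Adam(params, lr=self.learning_rate)

        weights = None
        if self.class_weight == "balanced":
            counts = np.bincount(labels[train_mask], minlength=2)
            w_class = len(labels[train_mask]) / (2.0 * np.maximum(counts, 1))
            weights = w_class[labels]

        batches = self._make_batches(graph, train_mask)
        tr_idx = np.flatnonzero(train_mask)
        val_idx = np.flatnonzero(val_mask)
        history = []
        best = (np.inf, None, 0)
        n_increase = 0
        prev_val = np.inf
        for epoch in range(1, self.max_epochs + 1):
            if batches is None:
                # one forward serves both losses; the validation loss (and
                # the checkpointed best state) refer to the parameters
                # entering the epoch
                opt.zero_grad()
                logits = self._logits(graph, cache)
                loss = ad.cross_entropy(
                    ad.gather_rows(logits, tr_idx), labels[tr_idx],
                    None if weights is None else weights[tr_idx])
                val_loss = float(ad.cross_entropy(
                    Tensor(logits.data[val_idx]), labels[val_idx],
                    None if weights is None else weights[val_idx]).data)
                train_loss = float(loss.data)
                self._check_finite(train_loss, val_loss, epoch)
                if val_loss < best[0]:
                    best = (val_loss,
                            [layer.state_dict() for layer in self.layers_],
                            epoch)
                loss.backward()
                opt.step()
            else:
                train_loss = self._train_epoch(graph, cache, batches, opt,
                                               labels, train_mask, weights)
                val_loss = self._eval_loss(graph, cache, labels, val_mask,
                                           weights)
                self._check_finite(train_loss, val_loss, epoch)
                if val_loss < best[0]:
                    best = (val_loss,
                            [layer.state_dict() for layer in self.layers_],
                            epoch)
            history.append((train_loss, val_loss))
            n_increase = n_increase + 1 if val_loss > prev_val else 0
            prev_val = val_loss
            if n_increase >= self.patience:
                break
        if best[1] is not None:
            for layer, state in zip(self.layers_, best[1]):
                layer.load_state_dict(state)
        self.history_ = pd.DataFrame(history, columns=["train_loss", "val_loss"])
        self.stopped_epoch_ = len(history)
        self.best_epoch_ = best[2]
        self.best_val_loss_ = best[0]
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = graph.node_features.shape[1]
        return self

    @staticmethod
    def _check_finite(train_loss, val_loss, epoch):
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch} "
                f"(train={train_loss}, val={val_loss}); lower the "
                "learning rate or check feature scaling")

    def _make_batches(self, graph, train_mask):
        """Patient-complete node batches; full graph when it fits."""
        n = graph.n_nodes
        if n <= self.batch_size or isinstance(graph, HeteroGraph):
            return None
        patient_of_node = graph.meta.get("patient_of_node")
        if patient_of_node is None:
            return None  # no grouping available: train full-graph
        patient_of_node = np.asarray(patient_of_node)
        rng = np.random.default_rng(self.random_state)
        patients = rng.permutation(np.unique(patient_of_node))
        nodes_of = pd.Series(np.arange(n)).groupby(patient_of_node).apply(
            lambda s: s.to_numpy())
        batches, current, size = [], [], 0
        for p in patients:
            nodes = nodes_of[p]
            if size + len(nodes) > self.batch_size and current:
                batches.append(np.concatenate(current))
                current, size = [], 0
            current.append(nodes)
            size += len(nodes)
        if current:
            batches.append(np.concatenate(current))
        return batches

    def _train_epoch(self, graph, cache, batches, opt, labels, train_mask,
                     weights):
        if batches is None:
            loss_val = self._step(graph, cache, opt, labels, train_mask,
                                  weights)
            return loss_val
        total, n_nodes = 0.0, 0
        for batch in batches:
            sub, sub_mask, sub_labels, sub_w = _subgraph(
                graph, batch, train_mask, labels, weights)
            if not sub_mask.any():
                continue
            sub_cache = EdgeCache(sub.edges, sub.n_nodes)
            loss_val = self._step(sub, sub_cache, opt, sub_labels, sub_mask,
                                  sub_w)
            total += loss_val * sub_mask.sum()
            n_nodes += sub_mask.sum()
        return total / max(n_nodes, 1)

    def _step(self, graph, cache, opt, labels, mask, weights):
        opt.zero_grad()
        logits = self._logits(graph, cache)
        idx = np.flatnonzero(mask)
        loss = ad.cross_entropy(
            ad.gather_rows(logits, idx), labels[idx],
            None if weights is None else weights[idx])
        loss.backward()
        opt.step()
        return float(loss.data)

    def _eval_loss(self, graph, cache, labels, mask, weights):
        logits = self._logits(graph, cache)
        idx = np.flatnonzero(mask)
        loss = ad.cross_entropy(
            Tensor(logits.data[idx]), labels[idx],
            None if weights is None else weights[idx])
        return float(loss.data)

    # -- inference ---------------------------------------------------------

    def predict_proba(self, graph) -> np.ndarray:
        self._check_fitted()
        if graph.node_features.shape[1] != self.n_features_in_:
            raise ValueError(
                f"graph has {graph.node_features.shape[1]} features; model "
                f"was fitted with {self.n_features_in_}")
        logits = self._logits(graph, self._cache(graph))
        return _softmax(logits.data)

    def predict(self, graph) -> np.ndarray:
        return (self.predict_proba(graph)[:, 1] >= 0.5).astype(np.int64)

    def extract_attention(self, graph) -> pd.DataFrame:
        """Run a forward pass and return all attention coefficients.

        One row per (layer, head, arc); self-loop arcs are included. Within
        each (layer, head, target) the weights sum to 1.
        """
        self._check_fitted()
        if self.layer_type not in ("gat", "gatv2"):
            raise ValueError("attention extraction requires a gat/gatv2 model")
        cache = self._cache(graph)
        self._logits(graph, cache)
        frames = []
        for li, layer in enumerate(self.layers_):
            if not isinstance(layer, GATLayer):
                continue
            for hi, alpha in enumerate(layer.last_attention_):
                frames.append(pd.DataFrame({
                    "layer": li, "head": hi,
                    "source": cache.src_sl, "target": cache.tgt_sl,
                    "weight": alpha,
                }))
        return pd.concat(frames, ignore_index=True)

    def _check_fitted(self):
        if not hasattr(self, "layers_"):
            raise ValueError("model is not fitted")

    # -- persistence ---------------------------------------------------------

    def save(self, directory) -> None:
        """Checkpoint as ``{params.npz, model_spec.json, history.csv}``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self._check_fitted()
        flat = {}
        for i, layer in enumerate(self.layers_):
            for k, v in layer.state_dict().items():
                flat[f"layer{i}::{k}"] = v
        np.savez(d / "params.npz", **flat)
        (d / "model_spec.json").write_text(json.dumps(
            {**self.get_params(),
             "stopped_epoch": int(self.stopped_epoch_),
             "best_epoch": int(self.best_epoch_)}, indent=2))
        self.history_.to_csv(d / "history.csv", index=False)


def _subgraph(graph: Graph, nodes: np.ndarray, mask, labels, weights):
    """Induced subgraph on ``nodes`` with remapped edge indices."""
    remap = -np.ones(graph.n_nodes, dtype=np.int64)
    remap[nodes] = np.arange(len(nodes))
    e = graph.edges
    keep = (remap[e[:, 0]] >= 0) & (remap[e[:, 1]] >= 0)
    sub = Graph(
        node_features=graph.node_features[nodes],
        edges=remap[e[keep]],
        labels=labels[nodes],
        masks={}, feature_names=graph.feature_names, meta=graph.meta)
    return (sub, mask[nodes], labels[nodes],
            None if weights is None else weights[nodes])


def train_node_classifier(graph, model_spec: ModelSpec | None = None,
                          train_spec: TrainSpec | None = None
                          ) -> GraphNodeClassifier:
    """Train a node classifier from spec objects (thin wrapper)."""
    ms = model_spec or ModelSpec()
    ts = train_spec or TrainSpec()
    clf = GraphNodeClassifier(
        layer_type=ms.layer_type, n_layers=ms.n_layers,
        hidden_dim=ms.hidden_dim, n_heads=ms.n_heads,
        activation=ms.activation, learning_rate=ts.learning_rate,
        max_epochs=ts.max_epochs, patience=ts.patience,
        batch_size=ts.batch_size, class_weight=ts.class_weight,
        random_state=ts.seed)
    return clf.fit(graph)


def predict_proba(model: GraphNodeClassifier, graph) -> np.ndarray:
    """Per-node class probabilities (thin wrapper)."""
    return model.predict_proba(graph)


def extract_attention(model: GraphNodeClassifier, graph) -> pd.DataFrame:
    """All attention weights of a trained attention model (thin wrapper)."""
    return model.extract_attention(graph)
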