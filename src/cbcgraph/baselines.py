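"""Tabular baseline models for the similarity benchmarks.

Logistic regression and the tree-based models are tuned by grid search
with 10-fold cross-validation on the training split (small fixed grids,
logged with every fitted model). The neural-network baseline (``mlp``) is
a two-layer 128-unit perceptron trained with the same early-stopping
protocol as the graph models — it reuses the graph classifier with an
edgeless graph, so the optimizer, loss and stopping rule are identical by
construction.

External models exposing ``predict_proba`` (e.g. gradient-boosting
implementations) can be plugged into the benchmark reports through
:func:`wrap_external_model`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.tree import DecisionTreeClassifier

from .graphs import Graph
from .nn.classifier import GraphNodeClassifier

__all__ = ["BASELINE_GRIDS", "train_tabular_baseline", "TabularMLP",
           "wrap_external_model"]

#: Small fixed hyperparameter grids for the cross-validated baselines.
BASELINE_GRIDS: dict[str, dict] = {
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
    "decision_tree": {"max_depth": [3, 5, 10, None],
                      "min_samples_leaf": [1, 5, 20]},
    "random_forest": {"n_estimators": [100], "max_depth": [5, 10, None],
                      "min_samples_leaf": [1, 5]},
}


class TabularMLP(BaseEstimator):
    """Two-layer perceptron under the graph-model training protocol.

    Wraps :class:`GraphNodeClassifier` with ``layer_type='mlp'`` on an
    edgeless graph; requires an explicit validation set for early stopping
    (patience 10 by default, like the similarity-graph models).
    """

    def __init__(self, hidden_dim=128, learning_rate=3e-4, max_epochs=10_000,
                 patience=10, random_state=0):
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if X_val is None:
            # hold out a deterministic 10% validation slice
            rng = np.random.default_rng(self.random_state)
            idx = rng.permutation(len(X))
            n_val = max(1, len(X) // 10)
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=np.int64)
        features = np.vstack([X, X_val])
        labels = np.concatenate([y, y_val])
        n_tr = len(X)
        masks = {
            "train": np.arange(len(features)) < n_tr,
            "validation": np.arange(len(features)) >= n_tr,
        }
        graph = Graph(node_features=features,
                      edges=np.empty((0, 2), dtype=np.int64),
                      labels=labels, masks=masks)
        self.clf_ = GraphNodeClassifier(
            layer_type="mlp", hidden_dim=self.hidden_dim,
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            patience=self.patience, random_state=self.random_state).fit(graph)
        self.history_ = self.clf_.history_
        self.stopped_epoch_ = self.clf_.stopped_epoch_
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        graph = Graph(node_features=X, edges=np.empty((0, 2), dtype=np.int64),
                      labels=np.zeros(len(X), dtype=np.int64))
        return self.clf_.predict_proba(graph)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)


def train_tabular_baseline(name: str, X, y, folds: int = 10, seed: int = 0,
                           X_val=None, y_val=None):
    """Fit one tabular baseline; returns a model with ``predict_proba``.

    ``logistic_regression``, ``decision_tree`` and ``random_forest`` are
    grid-searched with ``folds``-fold cross-validation; the grid and the
    chosen hyperparameters are stored on the returned object
    (``searched_grid_`` / ``chosen_params_``). ``mlp`` expects standardized
    inputs and follows the early-stopping protocol of the graph models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y")
    if name == "mlp":
        model = TabularMLP(random_state=seed).fit(X, y, X_val, y_val)
        model.searched_grid_ = {}
        model.chosen_params_ = model.get_params()
        return model
    estimators = {
        "logistic_regression": LogisticRegression(max_iter=2000,
                                                  random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
    }
    if name not in estimators:
        raise ValueError(f"unknown baseline {name!r}")
    grid = BASELINE_GRIDS[name]
    search = GridSearchCV(estimators[name], grid, cv=folds,
                          scoring="roc_auc", n_jobs=1)
    search.fit(X, y)
    model = search.best_estimator_
    model.searched_grid_ = grid
    model.chosen_params_ = search.best_params_
    return model


def wrap_external_model(model):
    """Adapter for externally trained models exposing ``predict_proba``."""
    if not hasattr(model, "predict_proba"):
        raise TypeError("external model must expose predict_proba")
    return model
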