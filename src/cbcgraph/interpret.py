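"""Model-agnostic interpretability: partial dependence, normalized-variance
feature importance, model clustering, and attention summaries.

Partial dependence sweeps one raw-scale feature over a grid (100 points
between its 5th and 95th percentile, or the unique values when fewer),
substitutes the grid value into every row, re-applies the required
transformations (standardization, graph feature assembly), and records
the mean predicted sepsis probability. The variance of each feature's
curve, normalized over the sum of variances for the model, gives a
feature importance in [0, 1] that sums to 1 per model. Importance rows of
several models are compared by hierarchical clustering (Euclidean
distance, average linkage).

Graph topology is held fixed during the sweep: similarity graphs are not
rebuilt per grid value, so the curve isolates the feature's effect on the
trained predictor rather than on the graph construction (a flag rebuilds
the k-NN graph for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .cohort import FEATURES

__all__ = ["PDPCurve", "partial_dependence", "importance_from_pdp",
           "cluster_models", "summarize_attention_by_label",
           "ATTENTION_QUANTILES"]

#: Quantile cut points reported in attention summaries.
ATTENTION_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass(frozen=True)
class PDPCurve:
    """Partial-dependence curve of one feature for one model."""

    feature: str
    grid: np.ndarray
    average_prediction: np.ndarray

    def variance(self) -> float:
        return float(np.var(self.average_prediction))

    def as_frame(self, model: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "model": model, "feature": self.feature,
            "grid_value": self.grid,
            "avg_prediction": self.average_prediction})


def partial_dependence(predict_fn, cohort: pd.DataFrame, feature: str,
                       grid_resolution: int = 100,
                       split: str | None = None) -> PDPCurve:
    """Average predicted sepsis probability as one feature is swept.

    ``predict_fn`` maps a cohort-shaped DataFrame to per-row sepsis
    probabilities in [0, 1] and is responsible for any transformation the
    model needs (standardization, graph assembly). The grid value is
    substituted into every row of the cohort — graph-based predictors see
    the whole (fixed-topology) graph — while the recorded average and the
    grid percentiles are restricted to the rows of ``split`` when given.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of "
                         f"{FEATURES}")
    mask = (np.ones(len(cohort), dtype=bool) if split is None
            else (cohort["split"] == split).to_numpy())
    if not mask.any():
        raise ValueError("no rows to average over")
    values = cohort.loc[mask, feature].to_numpy(dtype=float)
    unique = np.unique(values)
    if unique.size < grid_resolution:
        grid = unique
    else:
        lo, hi = np.percentile(values, [5, 95])
        grid = np.linspace(lo, hi, grid_resolution)

    avg = np.empty(grid.size)
    work = cohort.copy()
    for i, g in enumerate(grid):
        work[feature] = g
        p = np.asarray(predict_fn(work), dtype=float)
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("predict_fn returned values outside [0, 1]")
        avg[i] = p[mask].mean()
    return PDPCurve(feature=feature, grid=grid, average_prediction=avg)


def importance_from_pdp(curves: dict[str, PDPCurve] | list[PDPCurve]
                        ) -> pd.Series:
    """Normalized-variance importance of one model's curves.

    ``importance_f = Var(curve_f) / sum_g Var(curve_g)``; the values lie in
    [0, 1] and sum to 1. All-constant curves make the importance undefined
    and raise rather than silently returning zeros.
    """
    if not isinstance(curves, dict):
        curves = {c.feature: c for c in curves}
    if len(curves) < 2:
        raise ValueError("need curves for at least 2 features")
    var = pd.Series({f: c.variance() for f, c in curves.items()})
    total = var.sum()
    if total == 0:
        raise ValueError("all partial-dependence curves are constant; "
                         "importance is undefined")
    return var / total


def cluster_models(importance: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering of models.

    ``importance`` is a (models x features) matrix of normalized variances;
    returns the scipy linkage matrix (Euclidean distance, average linkage).
    """
    if importance.shape[0] < 2:
        raise ValueError("need at least 2 models to cluster")
    return linkage(importance.to_numpy(dtype=float), method="average",
                   metric="euclidean")


def plot_pdp_curves(curves_by_model: dict[str, dict[str, PDPCurve]],
                    path) -> None:
    """One line chart per feature, one line per model (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    features = sorted({f for cs in curves_by_model.values() for f in cs})
    fig, axes = plt.subplots(1, len(features),
                             figsize=(3 * len(features), 3), squeeze=False)
    for ax, feature in zip(axes[0], features):
        for model, cs in curves_by_model.items():
            c = cs[feature]
            ax.plot(c.grid, c.average_prediction, label=model)
        ax.axhline(0.5, ls=":", c="k", lw=0.8)
        ax.set_xlabel(feature)
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].set_ylabel("average sepsis probability")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importance_heatmap(importance: pd.DataFrame, path) -> None:
    """Clustered heatmap of normalized-variance importances (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list

    order = (leaves_list(cluster_models(importance))
             if importance.shape[0] >= 2 else np.arange(len(importance)))
    data = importance.iloc[order]
    fig, ax = plt.subplots(
        figsize=(1.2 * importance.shape[1], 0.6 * len(importance) + 1.5))
    im = ax.imshow(data.to_numpy(), cmap="viridis", vmin=0, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(data)), data.index)
    fig.colorbar(im, ax=ax, label="normalized variance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summarize_attention_by_label(records: pd.DataFrame,
                                 labels: np.ndarray) -> pd.DataFrame:
    """Group attention weights by label concordance of their arcs.

    Every non-self-loop arc is assigned to ``same_label`` or
    ``different_label`` from (label(source), label(target)); self-loops are
    reported separately. Per (layer, group): count, mean, SD and the
    quantiles in :data:`ATTENTION_QUANTILES`. An empty group appears with
    count 0 and NaN statistics rather than raising.
    """
    if len(records) == 0:
        raise ValueError("no attention records")
    labels = np.asarray(labels)
    src = records["source"].to_numpy()
    tgt = records["target"].to_numpy()
    if src.max() >= len(labels) or tgt.max() >= len(labels):
        raise ValueError("arc endpoint without a label")
    group = np.where(src == tgt, "self_loop",
                     np.where(labels[src] == labels[tgt],
                              "same_label", "different_label"))
    df = records.assign(group=group)
    out = []
    for layer in sorted(df["layer"].unique()):
        sub = df[df["layer"] == layer]
        for g in ("same_label", "different_label", "self_loop"):
            w = sub.loc[sub["group"] == g, "weight"].to_numpy()
            row = {"layer": layer, "group": g, "count": len(w),
                   "mean": np.nan, "sd": np.nan}
            row.update({f"q{int(q * 100):02d}": np.nan
                        for q in ATTENTION_QUANTILES})
            if len(w):
                row["mean"] = float(w.mean())
                row["sd"] = float(w.std())
                for q in ATTENTION_QUANTILES:
                    row[f"q{int(q * 100):02d}"] = float(np.quantile(w, q))
            out.append(row)
    return pd.DataFrame(out)
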