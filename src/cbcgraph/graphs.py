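"""Graph construction from CBC cohorts.

Five graph structures are supported, all with one node per measurement:

* a homogeneous k-nearest-neighbour similarity graph on the standardized
  seven input features (Euclidean distance),
* a heterogeneous similarity graph where measurements connect to
  percentile-interval nodes of each blood parameter, so that measurements
  are indirectly linked through similar laboratory values,
* three patient-centric temporal graphs: directed (past -> present message
  flow), reversed directed (future -> present), and undirected (both).

Edge lists are ordered ``(source, target)`` pairs of 0-based node indices;
messages flow from source to target. Positions are 1-based as in the
clinical ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import BLOOD_PARAMETERS, FEATURES, SPLITS

__all__ = [
    "CohortStandardizer",
    "Graph",
    "PercentileBin",
    "HeteroGraph",
    "fit_standardizer",
    "build_knn_similarity_graph",
    "compute_percentile_bins",
    "assign_bins",
    "build_hetero_similarity_graph",
    "build_patient_graph",
    "add_positional_encoding",
]

logger = logging.getLogger(__name__)


class CohortStandardizer:
    """Per-feature standard scaler fitted on one split of a cohort.

    Sklearn-style transformer: ``fit`` learns per-feature mean and SD
    (population SD, ddof=0) on the fitting split, ``transform`` maps
    ``x -> (x - mean) / sd``. Refusing constant features keeps downstream
    distances well defined.
    """

    def __init__(self, features: list[str] | None = None):
        self.features = list(features) if features is not None else list(FEATURES)

    def get_params(self, deep: bool = True) -> dict:
        return {"features": self.features}

    def set_params(self, **params) -> "CohortStandardizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, cohort: pd.DataFrame, split: str = "train") -> "CohortStandardizer":
        rows = cohort[cohort["split"] == split] if "split" in cohort else cohort
        if len(rows) == 0:
            raise ValueError(f"split {split!r} is empty")
        X = rows.loc[:, self.features].to_numpy(dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        bad = np.flatnonzero(self.scale_ <= 0)
        if bad.size:
            names = [self.features[i] for i in bad]
            raise ValueError(f"constant feature(s) on fitting split: {names}")
        self.fit_split_ = split
        return self

    def transform(self, cohort: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        X = cohort.loc[:, self.features].to_numpy(dtype=float)
        return (X - self.mean_) / self.scale_

    def fit_transform(self, cohort: pd.DataFrame, split: str = "train") -> np.ndarray:
        return self.fit(cohort, split).transform(cohort)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_

    def _check_fitted(self) -> None:
        if not hasattr(self, "mean_"):
            raise ValueError("standardizer is not fitted")


def fit_standardizer(cohort: pd.DataFrame, split: str = "train") -> CohortStandardizer:
    """Fit a :class:`CohortStandardizer` on one split (thin wrapper)."""
    return CohortStandardizer().fit(cohort, split=split)


@dataclass
class Graph:
    """Homogeneous node-classification graph.

    ``edges`` is an (E, 2) integer array of directed ``(source, target)``
    arcs; ``masks`` maps split names to boolean node masks.
    """

    node_features: np.ndarray
    edges: np.ndarray
    labels: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_features(self) -> int:
        return self.node_features.shape[1]

    def validate(self) -> "Graph":
        e = self.edges
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array")
        if e.size and (e.min() < 0 or e.max() >= self.n_nodes):
            raise ValueError("edge endpoint out of range")
        if e.size and len(np.unique(e, axis=0)) != len(e):
            raise ValueError("duplicate arcs")
        return self

    def save(self, directory) -> None:
        """Serialize to ``{nodes.csv, edges.tsv, meta.json}``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cols = self.feature_names or [f"f{i}" for i in range(self.n_features)]
        nodes = pd.DataFrame(self.node_features, columns=cols)
        nodes["label"] = self.labels
        split = np.array(["" for _ in range(self.n_nodes)], dtype=object)
        for tag, m in self.masks.items():
            split[m] = tag
        nodes["split"] = split
        nodes.to_csv(d / "nodes.csv", index=False)
        pd.DataFrame(self.edges, columns=["source", "target"]).assign(
            edge_type="homogeneous").to_csv(d / "edges.tsv", sep="\t", index=False)
        (d / "meta.json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def load(cls, directory) -> "Graph":
        d = Path(directory)
        nodes = pd.read_csv(d / "nodes.csv")
        edges = pd.read_csv(d / "edges.tsv", sep="\t")
        meta = json.loads((d / "meta.json").read_text())
        feature_names = [c for c in nodes.columns if c not in ("label", "split")]
        masks = {tag: (nodes["split"] == tag).to_numpy()
                 for tag in nodes["split"].unique()}
        return cls(
            node_features=nodes.loc[:, feature_names].to_numpy(dtype=float),
            edges=edges.loc[:, ["source", "target"]].to_numpy(dtype=np.int64),
            labels=nodes["label"].to_numpy(dtype=np.int64),
            masks=masks, feature_names=feature_names, meta=meta)


def split_masks(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    return {tag: (cohort["split"] == tag).to_numpy() for tag in SPLITS}


def build_knn_similarity_graph(
    X_std: np.ndarray,
    k: int = 5,
    labels: np.ndarray | None = None,
    masks: dict[str, np.ndarray] | None = None,
    symmetric: bool = False,
    chunk_size: int = 2048,
) -> Graph:
    """Homogeneous k-nearest-neighbour similarity graph.

    Every node ``v`` receives one arc ``(u, v)`` from each of its
    ``min(k, N-1)`` nearest neighbours by Euclidean distance on the
    standardized features (self excluded). Ties are broken by node index,
    making the construction deterministic. With ``symmetric=True`` the
    reversed arcs are added as well (duplicates removed).
    """
    X = np.asarray(X_std, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("k-NN graph needs at least 2 nodes")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        logger.warning("k=%d >= N=%d; connecting every node to all others", k, n)
        k = n - 1

    sq = np.einsum("ij,ij->i", X, X)
    sources = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (X[start:stop] @ X.T)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        # stable argsort breaks distance ties by node index
        order = np.argsort(np.maximum(d2, 0.0), axis=1, kind="stable")
        sources[start:stop] = order[:, :k]

    targets = np.repeat(np.arange(n), k)
    edges = np.column_stack([sources.reshape(-1), targets])
    if symmetric:
        edges = np.unique(np.vstack([edges, edges[:, ::-1]]), axis=0)
    g = Graph(
        node_features=X,
        edges=edges,
        labels=(np.zeros(n, dtype=np.int64) if labels is None
                else np.asarray(labels, dtype=np.int64)),
        masks=masks or {},
        feature_names=list(FEATURES) if X.shape[1] == len(FEATURES) else [],
        meta={"kind": "knn_similarity", "k": int(k), "symmetric": symmetric},
    )
    return g.validate()


@dataclass(frozen=True)
class PercentileBin:
    """One percentile interval of a blood parameter.

    Node features of a bin are ``(lower_value, upper_value,
    upper_percentile)``: the minimum and maximum absolute value observed in
    the interval's range on the training data and the interval's upper
    percentile as a fraction.
    """

    parameter: str
    lower_value: float
    upper_value: float
    upper_percentile: float

    def features(self) -> np.ndarray:
        return np.array([self.lower_value, self.upper_value,
                         self.upper_percentile], dtype=float)


def compute_percentile_bins(values, m: int = 10,
                            parameter: str = "value") -> list[PercentileBin]:
    """Discretize one blood parameter into ``m`` percentile intervals.

    Boundaries sit at the ``i/m`` quantiles of the training values; bins
    partition the observed range and each training value maps to exactly
    one bin. Percentile discretization keeps the intervals insensitive to
    outliers.
    """
    v = np.asarray(values, dtype=float)
    if m < 2:
        raise ValueError("m must be >= 2")
    if np.unique(v).size < m:
        raise ValueError(
            f"only {np.unique(v).size} distinct values for {parameter!r}; "
            f"choose m <= that")
    qs = np.quantile(v, np.arange(m + 1) / m)
    bins = []
    for i in range(m):
        bins.append(PercentileBin(
            parameter=parameter,
            lower_value=float(qs[i]),
            upper_value=float(qs[i + 1]),
            upper_percentile=(i + 1) / m,
        ))
    return bins


def assign_bins(values, bins: list[PercentileBin]) -> np.ndarray:
    """Map values to bin indices; out-of-range values clamp to the
    boundary bins."""
    uppers = np.array([b.upper_value for b in bins])
    idx = np.searchsorted(uppers[:-1], np.asarray(values, dtype=float),
                          side="left")
    return np.clip(idx, 0, len(bins) - 1)


@dataclass
class HeteroGraph:
    """Heterogeneous similarity graph: measurements + percentile-bin nodes.

    ``bin_features[p]`` is an (m, 3) array for blood parameter ``p``;
    ``edges[(src_type, dst_type)]`` holds typed (E, 2) arc lists. Every
    measurement has exactly one bin edge per blood parameter, in both
    directions, so two message-passing layers let measurements exchange
    information through shared bins.
    """

    node_features: np.ndarray
    bins: dict[str, list[PercentileBin]]
    bin_features: dict[str, np.ndarray]
    edges: dict[tuple[str, str], np.ndarray]
    labels: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def measurement_bin_degree(self) -> np.ndarray:
        """Bin-degree of each measurement node (5 when all parameters bound)."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for (src, dst), e in self.edges.items():
            if src == "measurement" and dst != "measurement":
                np.add.at(deg, e[:, 0], 1)
        return deg


def build_hetero_similarity_graph(
    cohort: pd.DataFrame,
    m: int = 10,
    standardizer: CohortStandardizer | None = None,
    fit_split: str = "train",
) -> HeteroGraph:
    """Build the heterogeneous percentile-interval similarity graph.

    Bins and the standardizer are fitted on the training split only;
    measurements from test splits with out-of-range values clamp to the
    first/last bin of the parameter.
    """
    if standardizer is None:
        standardizer = CohortStandardizer().fit(cohort, split=fit_split)
    X = standardizer.transform(cohort)
    train = cohort[cohort["split"] == fit_split]
    if len(train) == 0:
        raise ValueError(f"split {fit_split!r} is empty")

    bins: dict[str, list[PercentileBin]] = {}
    bin_feats: dict[str, np.ndarray] = {}
    edges: dict[tuple[str, str], np.ndarray] = {}
    n = len(cohort)
    for p in BLOOD_PARAMETERS:
        pb = compute_percentile_bins(train[p].to_numpy(dtype=float), m=m,
                                     parameter=p)
        bins[p] = pb
        bin_feats[p] = np.stack([b.features() for b in pb])
        member = assign_bins(cohort[p].to_numpy(dtype=float), pb)
        meas_to_bin = np.column_stack([np.arange(n), member])
        edges[("measurement", p)] = meas_to_bin
        edges[(p, "measurement")] = meas_to_bin[:, ::-1].copy()

    return HeteroGraph(
        node_features=X,
        bins=bins,
        bin_features=bin_feats,
        edges=edges,
        labels=cohort["label"].to_numpy(dtype=np.int64),
        masks=split_masks(cohort),
        feature_names=list(standardizer.features),
        meta={"kind": "hetero_similarity", "m": int(m)},
    )


def build_patient_graph(
    cohort: pd.DataFrame,
    mode: str = "reversed",
    standardizer: CohortStandardizer | None = None,
    fit_split: str = "train",
) -> Graph:
    """Patient-centric temporal graph over a cohort's measurements.

    Arcs never cross patients. Within a patient with measurements at
    positions ``1..n``:

    * ``directed``: arc ``u -> v`` for every pair with position(u) <
      position(v), so each measurement receives messages from its past;
    * ``reversed``: arc ``u -> v`` for position(u) > position(v) (messages
      from the future);
    * ``undirected``: both arcs for every pair.

    Arc counts per patient are n(n-1)/2, n(n-1)/2 and n(n-1) respectively;
    singleton patients contribute no arcs.
    """
    if mode not in ("directed", "reversed", "undirected"):
        raise ValueError(f"unknown mode {mode!r}")
    if standardizer is None:
        standardizer = CohortStandardizer().fit(cohort, split=fit_split)
    X = standardizer.transform(cohort)

    idx = np.arange(len(cohort))
    srcs, tgts = [], []
    pos = cohort["position"].to_numpy()
    for _, grp in pd.Series(idx).groupby(cohort["patient_id"].to_numpy(),
                                         sort=False):
        g = grp.to_numpy()
        if len(g) < 2:
            continue
        g = g[np.argsort(pos[g], kind="stable")]
        a, b = np.triu_indices(len(g), k=1)
        early, late = g[a], g[b]  # position(early) < position(late)
        if mode in ("directed", "undirected"):
            srcs.append(early)
            tgts.append(late)
        if mode in ("reversed", "undirected"):
            srcs.append(late)
            tgts.append(early)
    if srcs:
        edges = np.column_stack([np.concatenate(srcs), np.concatenate(tgts)])
    else:
        edges = np.empty((0, 2), dtype=np.int64)

    return Graph(
        node_features=X,
        edges=edges,
        labels=cohort["label"].to_numpy(dtype=np.int64),
        masks=split_masks(cohort),
        feature_names=list(standardizer.features),
        meta={"kind": f"patient_{mode}", "mode": mode},
    ).validate()


def add_positional_encoding(graph: Graph, cohort: pd.DataFrame,
                            scheme: str = "linear", dim: int = 4) -> Graph:
    """Append positional encodings of each measurement's sequence rank.

    ``linear`` (default) appends a single scalar: the 1-based position
    standard-normalized over the training split — a monotone feature that
    represents later measurements with higher attribute values. ``sinusoidal``
    appends ``dim`` sine/cosine channels plus the monotone scalar.
    ``none`` returns the graph unchanged.
    """
    if scheme == "none":
        return graph
    if len(cohort) != graph.n_nodes:
        raise ValueError("cohort rows must align with graph nodes")
    pos = cohort["position"].to_numpy(dtype=float)
    train = graph.masks.get("train")
    ref = pos[train] if train is not None and train.any() else pos
    mu, sd = ref.mean(), ref.std()
    scalar = (pos - mu) / (sd if sd > 0 else 1.0)

    if scheme == "linear":
        extra = scalar[:, None]
        names = ["pos_enc"]
    elif scheme == "sinusoidal":
        freqs = 1.0 / (10.0 ** (2 * np.arange(dim // 2) / max(dim, 2)))
        ang = pos[:, None] * freqs[None, :]
        extra = np.concatenate(
            [scalar[:, None], np.sin(ang), np.cos(ang)], axis=1)
        names = ["pos_enc"] + [f"pos_sin{i}" for i in range(dim // 2)] \
            + [f"pos_cos{i}" for i in range(dim // 2)]
    else:
        raise ValueError(f"unknown positional-encoding scheme {scheme!r}")

    return Graph(
        node_features=np.concatenate([graph.node_features, extra], axis=1),
        edges=graph.edges,
        labels=graph.labels,
        masks=graph.masks,
        feature_names=(graph.feature_names + names
                       if graph.feature_names else []),
        meta={**graph.meta, "positional_encoding": scheme},
    )
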