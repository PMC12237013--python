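import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from cbcgraph.cohort import COHORT_COLUMNS, GeneratorConfig, generate_cohort
from cbcgraph.graphs import Graph


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient cohort with elevated prevalence so every split has
    both classes."""
    return generate_cohort(GeneratorConfig(
        n_patients=200, seed=7, sepsis_measurement_prevalence=0.08))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture()
def toy_cohort():
    """Hand-built 4-patient cohort; descriptor fractions enumerated by hand.

    Patients: A singleton sepsis; B positions 1-3, sepsis at 3 (last);
    C positions 1-2, sepsis at 1 (not last); D singleton control.
    Sepsis measurements: 3; singletons among them: 1 (A) -> 1/3;
    in-sequence sepsis: B3 (last) and C1 (not last) -> last fraction 1/2.
    """
    rows = [
        ("A", 1, 70, 1, 7.5, 4.0, 15.0, 95.0, 120.0, 1, "train"),
        ("B", 1, 60, 0, 8.8, 4.8, 6.0, 88.0, 260.0, 0, "train"),
        ("B", 2, 60, 0, 8.5, 4.7, 7.5, 89.0, 240.0, 0, "train"),
        ("B", 3, 60, 0, 7.8, 4.3, 14.0, 93.0, 150.0, 1, "train"),
        ("C", 1, 55, 1, 8.0, 4.5, 13.0, 92.0, 160.0, 1, "validation"),
        ("C", 2, 55, 1, 8.9, 4.9, 6.5, 87.0, 250.0, 0, "validation"),
        ("D", 1, 40, 0, 9.1, 5.0, 5.5, 86.0, 280.0, 0, "internal_test"),
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def random_graph(rng, n_nodes=8, n_features=5, p_edge=0.35, labels=None):
    """Random directed graph without self-arcs or duplicates."""
    X = rng.normal(size=(n_nodes, n_features))
    pairs = [(u, v) for u in range(n_nodes) for v in range(n_nodes) if u != v]
    mask = rng.random(len(pairs)) < p_edge
    edges = np.array([p for p, m in zip(pairs, mask) if m],
                     dtype=np.int64).reshape(-1, 2)
    if labels is None:
        labels = rng.integers(0, 2, size=n_nodes)
    return Graph(node_features=X, edges=edges,
                 labels=np.asarray(labels, dtype=np.int64))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
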