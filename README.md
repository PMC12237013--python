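# cbcgraph

Graph-based sepsis classification on complete blood count (CBC) time
series.

Routine hospital laboratory data arrive as short, irregular sequences of
blood counts per patient: hemoglobin, red blood cells (RBC), white blood
cells (WBC), mean corpuscular volume (MCV) and platelets, plus age and
biological sex, each draw labelled *sepsis* or *control*. Standard tabular
classifiers treat every draw as independent and discard the connection
between a patient's measurements. `cbcgraph` is a tested pipeline for
studying when message-passing networks on graphs built from such data beat
tabular models — and *why*, separating feature-driven gains from gains
induced purely by graph structure.

The package is aimed at methods researchers in clinical machine learning.
It contains:

- **`cbcgraph.cohort`** — a seeded synthetic cohort generator that emulates
  the structural biases of real sepsis CBC data: variable-length sequences,
  strong class imbalance, ≈2/3 of sepsis cases as singleton measurements,
  in-sequence sepsis concentrated at the final position (≈92%),
  class-conditional feature shifts (WBC↑, platelets↓, hemoglobin↓, MCV↑,
  age↑) and an external test site with a mild distribution shift.
- **`cbcgraph.graphs`** — five graph constructions over the measurements:
  a homogeneous k-nearest-neighbour similarity graph on standardized
  features; a heterogeneous graph linking measurements to percentile-bin
  nodes of each blood parameter; and directed / reversed-directed /
  undirected patient-centric temporal graphs, with optional positional
  encodings.
- **`cbcgraph.nn`** — SAGE-mean, GCN, GAT, GATv2 and GIN layers written
  from their defining update rules on a small numpy reverse-mode autodiff
  engine, wrapped in a scikit-learn-style `GraphNodeClassifier`
  (`fit` / `predict_proba`) with validation-loss early stopping and
  attention-weight capture.
- **`cbcgraph.baselines` / `cbcgraph.metrics`** — grid-searched tabular
  baselines (logistic regression, decision tree, random forest, and a
  two-layer perceptron trained under the identical protocol), AUROC
  (rank formulation), F1-macro, MCC, and the uniform-noise-feature
  injector for robustness studies.
- **`cbcgraph.interpret`** — graph-compatible partial dependence,
  normalized-variance feature importance (per model, sums to 1),
  average-linkage model clustering, and attention summaries grouped by
  label concordance of each arc.
- **`cbcgraph.experiments` / CLI** — four orchestrated experiments
  (`benchmark-similarity`, `benchmark-patient`, `noise`, `interpret`)
  with manifests, seed averaging and a leakage guard that poisons
  test-split labels during training.

## The core idea

For node `v` with in-neighbourhood `N(v)`, one message-passing layer
computes `h'_v = act(combine(h_v, agg({W h_u : u ∈ N(v)})))`; a graph
attention layer replaces the plain mean by softmax-normalized weights
`α_uv` per arc. On a *reversed-directed* patient graph (arcs flow from
later to earlier measurements) a sepsis measurement at the end of a
sequence receives no messages and keeps its elevated features undiluted,
while control measurements average away noise from their follow-ups — a
structure-induced bias that mirrors how in-sequence sepsis concentrates at
final positions, and the mechanism behind the large AUROC gains of
reversed patient graphs over similarity graphs and tabular models.

## Worked example

```python
from cbcgraph import (GeneratorConfig, generate_cohort, cohort_stats,
                      fit_standardizer, build_patient_graph, auroc,
                      GraphNodeClassifier)

cohort = generate_cohort(GeneratorConfig(seed=7))
stats = cohort_stats(cohort)
print(f"measurements: {stats.n_measurements}, "
      f"sepsis prevalence: {stats.sepsis_prevalence:.4f}")
print(f"singleton sepsis fraction: {stats.singleton_sepsis_fraction:.3f}")
print(f"last-position sepsis fraction: {stats.last_position_sepsis_fraction:.3f}")

std = fit_standardizer(cohort)                      # fitted on train split
graph = build_patient_graph(cohort, mode="reversed", standardizer=std)
clf = GraphNodeClassifier(layer_type="gat", hidden_dim=64,
                          max_epochs=500, patience=5, random_state=0).fit(graph)
scores = clf.predict_proba(graph)[:, 1]
y = cohort["label"].to_numpy()
for split in ("internal_test", "external_test"):
    m = graph.masks[split]
    print(f"{split} AUROC: {auroc(y[m], scores[m]):.4f}")
```

Output:

```
measurements: 12383, sepsis prevalence: 0.0206
singleton sepsis fraction: 0.667
last-position sepsis fraction: 0.918
internal_test AUROC: 0.8858
external_test AUROC: 0.8972
```

The cohort reproduces the configured structural descriptors (2/3 singleton
sepsis; ~92% of in-sequence sepsis at the last position), and the
attention network on the reversed patient graph separates the rare sepsis
class well despite ~2% prevalence. Under the same 500-epoch protocol the
reversed graph outranks the undirected and directed variants and the
tabular perceptron — the structure-bias ordering the experiments module
quantifies (`cbcgraph benchmark-patient`).

The same pipeline is available from the shell:

```bash
cbcgraph generate --seed 7 --out cohort.csv
cbcgraph build-graph --cohort cohort.csv --kind reversed --pe linear --out graph/
cbcgraph train --cohort cohort.csv --model gat --graph reversed --out model/
cbcgraph benchmark-patient --seed 0 --out reports/
```

## Documentation

`docs/methods.md` describes the generative model of the synthetic cohort,
the exact layer update rules and training protocol, the interpretability
estimators, the numerical choices (tie-breaking, clamping, desk-scale
problem sizes) and the limitations of synthetic evaluation.
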