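# Methods

## Problem setting

Each observation is one complete blood count (CBC) draw of a hospitalized
adult: hemoglobin (mmol/L), red blood cells (Tpt/L), white blood cells
(Gpt/L), mean corpuscular volume (fL), platelets (Gpt/L), plus age
(years) and biological sex (0 = male, 1 = female), with a binary sepsis
label. Draws are grouped by patient and ordered by a 1-based position.
The task is node classification: predict the label of every measurement,
evaluated primarily by AUROC because the positive class is rare.

## Synthetic cohort model

The generator is the package's study bed; it emulates the *structure* of
routine hospital CBC data without modelling any real patient.

**Sequence lengths.** Per patient, length `L ~ Geometric(p)` on
`{1, 2, ...}` with `p = 1/mean_sequence_length` (default mean 2.5). This
gives ~40% singleton patients, so singleton sepsis occurs naturally.

**Label placement.** Sepsis labels are placed to match two structural
descriptors: a target fraction (default 2/3) of sepsis measurements
belong to singleton patients; among in-sequence sepsis (patients with
≥2 draws), a target fraction (default 0.9214) sits at the final position,
the remainder uniformly among earlier positions. Counts are rounded
expectations, so per-cohort fractions concentrate tightly around the
targets; seed means are verified to ±3 percentage points in the
acceptance suite. Measurement-level prevalence defaults to 2%.

**Features.** Each continuous feature is truncated-normal per class.
Defaults (control vs sepsis mean, SD):

| feature    | control      | sepsis       | truncation  |
|------------|--------------|--------------|-------------|
| age        | 58 (18)      | 66 (16)      | [18, 100]   |
| hemoglobin | 8.6 (1.0)    | 7.9 (1.1)    | [3, 12.5]   |
| rbc        | 4.6 (0.60)   | 4.25 (0.65)  | [1.5, 7.5]  |
| wbc        | 6.8 (1.9)    | 12.5 (4.5)   | [0.5, 60]   |
| mcv        | 89 (5.5)     | 92.5 (6.0)   | [60, 125]   |
| platelets  | 250 (70)     | 190 (80)     | [10, 1000]  |

The control WBC center sits in the physiological 4–8 Gpt/L range and
leukocytosis is deliberately the dominant effect (so interpretability
methods have a known planted signal to recover); thrombocytopenia, mild
anemia, raised MCV and older age are secondary shifts. Age and sex are
patient-level attributes (constant within a sequence; sepsis patients draw
age from the shifted distribution). A per-patient random intercept per
feature (0.25 × control SD) models within-patient correlation of repeated
draws — this is what within-patient message passing can denoise.

**Splits and site shift.** Patients are split 60/10/15/15 into
train/validation/internal-test/external-test; no patient straddles
splits. The external split receives small additive offsets per feature
(e.g., WBC +0.4 Gpt/L, platelets −10 Gpt/L) and 1.2× prevalence, a mild
two-site shift.

**What the generator does not model:** clinical interventions, feature
cross-correlations beyond the shared patient intercept, temporal trends
within a sequence, missingness, or the marginal distributions of any real
hospital laboratory. Passing results on this cohort therefore demonstrate that
the pipeline exploits the *structural* biases correctly, not that any
AUROC transfers to real hospital data.

## Graph constructions

All graphs share node features standardized per feature with the mean/SD
of the training split only (population SD; constant features are
rejected).

- **k-NN similarity graph** (default k = 5; k is a free parameter of the
  study, reported with every output): each node receives arcs from its
  `min(k, N−1)` Euclidean nearest neighbours, self excluded. Distance
  ties break by node index (stable argsort), making construction
  deterministic. The graph spans all splits jointly (transductive) with
  mask-restricted losses; a flag rebuilds per split instead.
- **Heterogeneous percentile graph** (default m = 10): each blood
  parameter is discretized into m percentile intervals of the training
  values; a bin node carries (interval minimum, interval maximum, upper
  percentile). Every measurement connects to exactly one bin per
  parameter, in both directions, so two layers let measurements exchange
  information through shared bins. Test-split values outside the training
  range clamp to the boundary bins.
- **Patient-centric graphs**: arcs only within a patient. `directed`
  sends each measurement to all later ones (past → present message flow),
  `reversed` the opposite, `undirected` both; a patient with n draws
  yields n(n−1)/2, n(n−1)/2 and n(n−1) arcs respectively.
- **Positional encodings**: the default scheme appends one scalar — the
  position standard-normalized over the train split — a monotone feature
  giving later draws higher attribute values; a sinusoidal multi-channel
  scheme is available.

## Message-passing layers and training

Layers are implemented from their update rules on an in-package numpy
reverse-mode autodiff engine (gradient-checked against central
differences; hot paths run as cached sparse-matrix products):

- SAGE-mean: `h'_v = act(W_s h_v + W_n · mean_{u→v} h_u + b)`; empty
  in-neighbourhoods contribute zeros.
- GCN: self-loops mandatory, symmetric normalization with
  `d̂ = in-degree + 1`.
- GAT / GATv2: self-loops mandatory; scores `leaky_relu(a_s·Wh_u +
  a_t·Wh_v)` (v1) or `a·leaky_relu(W_s h_u + W_t h_v)` (v2), softmax per
  target; heads concatenate in hidden layers and average at the output.
- GIN: `h'_v = MLP((1+ε)h_v + Σ_{u→v} h_u)`, two-layer MLP, ε = 0.

On the heterogeneous graph, layers keep one self-transform per node type
and one message transform per relation (mean aggregation for the SAGE
variant; sum + per-type MLP for the GIN variant — the natural typed
generalisation).

**Training protocol.** Two layers, cross-entropy without class weighting
(a `balanced` flag exists), Adam at learning rate 3e-4, up to 10,000
epochs with early stopping after the validation loss has risen for
`patience` consecutive epochs — 10 for similarity graphs and the tabular
perceptron, 5 for patient-centric graphs. Parameters from the
best-validation-loss epoch are restored (the loss is evaluated on the
parameters entering each epoch, so the checkpoint matches the logged
value exactly). Graphs larger than the 50,000-node batch limit train on
patient-complete node batches; at the package's cohort sizes training is
full-graph. Test masks are never read during training, and the experiment
runners additionally poison test labels before every fit.

**Desk-scale defaults.** The experiment runners use 64 hidden units and a
uniform cap of 500 epochs for *every* model (graph and tabular alike), the
attention-concordance analysis 1,500 epochs; with full-batch Adam at
3e-4 none of the models has fully converged at that budget, but the cap is
identical across models so ranking comparisons remain like-for-like. The
full-scale protocol (128 hidden units, 10,000 epochs) is available through
`ModelSpec`/`TrainSpec`.

## Baselines and metrics

Logistic regression, decision tree and random forest are tuned by grid
search (small fixed grids, logged per run) with 10-fold cross-validation
on the training split. The neural-network baseline is a two-layer
perceptron implemented as an edgeless graph model, so its optimizer, loss
and stopping rule are identical to the graph networks by construction.
AUROC uses the rank (Mann-Whitney) formulation with ties counted one
half; F1-macro and MCC are computed at probability threshold 0.5
(configurable; the threshold choice was an open design point). The
noise-robustness experiment appends 10 or 100 i.i.d. uniform-[0,1)
columns before standardization and reports AUROC deltas against the
noise-free run.

## Interpretability

**Partial dependence** sweeps one raw-scale feature over 100 evenly
spaced values between its 5th and 95th percentile (or its unique values
when fewer, e.g. sex → {0, 1}), substitutes the value into *every* row,
re-applies the train-split standardization, and averages the predicted
sepsis probability over the evaluation split (internal test by default;
which split the averages should use was an open question — it is a
parameter). Graph topology is held fixed during the sweep: rebuilding the
similarity graph per grid value would change the estimand and the cost by
a factor of the grid size; a flag enables rebuilding for sensitivity
analysis.

**Importance** of feature f for a model is `Var(curve_f) / Σ_g
Var(curve_g)` — in [0, 1], summing to 1 per model; all-constant curve
sets raise rather than return silent zeros. Models are compared by
hierarchical clustering of their importance rows (Euclidean distance,
average linkage, scipy's deterministic tie handling).

**Attention summaries** group every captured arc weight by label
concordance of its endpoints (self-loops reported separately) and report
count, mean, SD and the {5, 25, 50, 75, 95}% quantiles per layer. On
reversed patient graphs, trained attention gives label-concordant arcs
higher mean weight than discordant ones — the structure-bias signature
the acceptance suite checks across seeds.

## Numerical choices and degenerate inputs

- All floating point is float64; forward/backward passes are
  deterministic (single-threaded sparse products, seeded initialization).
- k-NN and clustering tie-breaks are by lowest index; percentile-bin
  boundaries are linear-interpolation quantiles, values on a boundary go
  to the lower bin.
- Cohorts with zero sepsis report descriptor fractions as undefined
  (`None`) instead of dividing by zero; single-class training masks and
  non-finite losses abort with diagnostics.
- `k ≥ N` degrades to the complete digraph with a logged warning;
  discretization demands at least m distinct training values.

## Limitations

- Synthetic evaluation only: no real-data ingestion, and published
  real-data AUROCs are not reproduction targets.
- Heterogeneous attention variants, boosting baselines and recurrent /
  convolutional sequence models are out of scope (an adapter accepts any
  external model exposing `predict_proba`).
- Partial dependence assumes feature independence; correlated features
  (e.g. hemoglobin and RBC) make the substituted rows partly unphysical,
  a known limitation of the estimator.
- At the desk-scale epoch budget the models are compared under equal
  compute rather than at full convergence.
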