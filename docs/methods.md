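# Methods

## Model and assumptions

fuzzimpute treats a dataset as a numeric feature matrix with an optional class
label. A missing cell is imputed from the k complete-case rows nearest to its
row in Euclidean distance, with the neighbors' values combined by a weighted
average whose weights come from a fuzzy membership function fitted to those
same values. The approach assumes:

- **MCAR missingness.** Neighbor eligibility conditions only on which cells
  are observed, not on why. Under MAR/NMAR mechanisms the complete-case
  neighborhood is a biased sample and no correction is attempted (a declared
  non-goal).
- **Numeric, comparably meaningful features.** Distances are unweighted
  Euclidean sums; features on wildly different scales will dominate the
  neighborhood unless normalized beforehand. (The benchmark harness normalizes
  *after* imputation, before classification, mirroring the evaluation
  protocol this package implements.)
- **Local exchangeability.** Rows close in feature space carry exchangeable
  values in the target column — the usual hot-deck/k-NN assumption.

## Neighbor selection

For a missing cell (r, t), the distance columns are all feature columns except
t, excluding the label column unless `include_label_in_distance=True`, and
further restricted to columns where row r itself is observed
(pairwise-available handling for rows with several missing cells). A candidate
row must be observed at t and at every distance column in use. Distances tie
toward the lower row index via a stable sort, making selection fully
deterministic. If fewer than k candidates exist, all are used; if none exist,
the cell falls back to its column mean.

## Membership functions

- **Triangular**, vertices (a, b, c) = (min, mean, max) of the neighbor
  values: 0 for x ≤ a; (x−a)/(b−a) for a < x ≤ b; (c−x)/(c−b) for b < x < c;
  0 for x ≥ c. Boundary conventions are exactly these inequalities; a
  zero-width branch contributes 0. Consequence: with k = 2, or whenever every
  neighbor value sits at the min or max, all weights vanish and the fallback
  (arithmetic mean of neighbor values) applies — the triangular imputer is
  effectively meaningful for k ≥ 3.
- **Gaussian**, exp(−(x−μ)²/(2σ²)) with μ the mean and σ the **population**
  standard deviation (divisor k) of the neighbor values. The population form
  is the parameterization that reproduces the published hand-calculation
  weights for the neighbor set {2, 1, 7} to ~1e-4; the sample form (divisor
  k−1) does not, and neither does the σ value printed alongside those weights,
  which is internally inconsistent and treated as a typo. The true exponential
  is used (not a truncated 2.718…); the difference is below any printed
  precision.

## Fallback chain

Imputation is total on any matrix without an entirely-missing feature column:

1. all neighbor values identical → impute that value;
2. all-zero triangular weights, or σ = 0 → arithmetic mean of neighbor values;
3. no eligible candidate rows → column mean of observed values.

Each fallback is logged (`fuzzimpute.imputation` logger) rather than silent.
No weights are invented where the membership formulas define none. With k = 1
both memberships reduce, via rule 1, to nearest-neighbor hot-deck imputation.

Every cell is imputed against the *original* matrix — freshly imputed values
are never recycled as neighbors — so the output is independent of the order in
which cells are processed. This is single-pass imputation by design; iterative
or chained refinement is out of scope.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `k` | 3 | neighbors per missing cell; benchmark sweeps {3, 5, 7, 9} |
| `membership` | triangular | triangular or gaussian weighting |
| `include_label_in_distance` | False | whether the class label joins the distance |
| `InjectionSpec.proportion` | — | fraction of feature cells blanked (MCAR), e.g. 0.05/0.10 |
| `SplitSpec.test_size` | 0.2 | held-out fraction, stratified by label |

Classifier hyperparameters are scikit-learn defaults except the neighbor
classifier, which is pinned to the Euclidean metric, and the multi-layer
perceptron, which gets `max_iter=500` and a seed; the decision tree is also
seeded. Each CLI run logs the tool version, effective configuration and seed.

## MCAR injection protocol

`inject_mcar` blanks exactly round(p·n·m) of the n·m feature cells: a seeded
random permutation of all cells is consumed greedily, skipping any cell whose
removal would leave its row with no observed feature. The label column is
never touched. The proportion is a fraction of *cells*, not rows, and the
request is rejected when the count exceeds n·(m−1) (the no-empty-row bound).
The skip rule slightly deviates from exact uniformity over cell subsets at
extreme proportions, but keeps the draw deterministic per seed and one-pass.

## Synthetic data: what it does and does not emulate

`generate_synthetic` draws a binary label with probability `class_balance`
(default 0.5) and independent unit-variance Gaussian features whose means
differ between classes by `effect_size` (default 2) within-class standard
deviations. This emulates the shape of small clinical classification tables —
hundreds of rows, tens of features, binary outcome — and gives every feature
class signal, so features are marginally correlated through the label. That
correlation is exactly what lets neighborhood-based imputation beat the pooled
column mean: neighbors tend to come from the right class.

It does **not** emulate heavy tails, mixed categorical/numeric columns,
within-class feature correlation, imbalanced multiclass labels, or structured
(MAR/NMAR) missingness. Passing tests on this generator therefore demonstrate
correctness of the mechanics and the directional advantage under favorable,
class-structured MCAR conditions — not performance on any particular real
dataset. Test-scale choices: the parameter-recovery check uses n = 500 rows,
10 features, effect size 2, 5% MCAR and 20 replicates; the benchmark
determinism check uses a 300-row table.

## Numerical choices

- Worked-example assertions use 1e-3 absolute tolerance (the source rounds
  inconsistently, e.g. a mean of 10/3 printed as 3.33); full precision is used
  internally.
- Min–max normalization fits min and range on the training split only, maps a
  constant column to 0, and does not clip test values, which may leave [0, 1].
- Binary accuracy goes through the explicit confusion-matrix counts with the
  larger label value as positive; multiclass accuracy generalizes to the
  trace of the confusion matrix over its total.
- Empty column sets, all-missing columns, empty listwise results and
  zero-total confusion matrices raise; they have no meaningful value.

## Known limitations

- Quadratic neighbor search (no spatial index); fine for the intended
  table sizes, slow beyond ~10⁵ rows.
- Single stratified split by default; repeated splits can be driven externally
  by varying the seed, but cross-validation is not built in.
- The triangular function's zero weight at both extremes means k = 2 always
  falls back; this follows from the published boundary conventions and is kept
  as specified.
- Listwise deletion can starve a class; the benchmark reports such cells as
  failed rather than aborting the sweep.
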