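# Methods

## The model

`qsarnet` fits quantitative structure–activity relationship (QSAR)
regression models: given a table of precomputed molecular descriptors
(MOE/CDK-style numeric columns) and one log-scale activity per compound
(pIC50, LAC50), it trains a fully connected feed-forward network

- hidden layers with tanh activation, `tanh(x) = (e^{2x} − 1)/(e^{2x} + 1)`;
- a single **linear** output node. Activities are unbounded log
  concentrations, so squashing the output through tanh would cap the
  dynamic range; the linear head was chosen deliberately and tanh is never
  applied to the output.

The default architecture is three hidden layers of 20 nodes. For a
five-descriptor input that gives 5·20 + 20·20 + 20·20 + 20·1 = 920
connection weights; depth and width grow freely through the configuration.
Biases are included by default (and excluded from both weight decay and the
weights-only parameter count, which reproduces the 920 figure).

## The cost function

Training minimizes

    J(W, λ) = −q² + (λ/2) · Σ_l Σ_i Σ_j (W^l_ij)²

where `q² = 1 − Σ(h(x_i) − y_i)² / Σ(y_i − ȳ)²` over the training set. The
denominator SST = Σ(y−ȳ)² is a constant of the training set, so J is an
affine transformation of the mean-squared-error cost: minimizing J is
*exactly* maximizing q², and the reported cost is directly interpretable as
a negated correlation coefficient plus the decay penalty. The identity
`J − decay = −1 + SSE/SST` holds to machine precision and is asserted in
the tests.

During mini-batch SGD the denominator stays **fixed at the full
training-set SST for the whole epoch** (it never changes between epochs
either, since the training set is fixed). This keeps the stochastic
gradient a constant rescaling of the MSE gradient, so the J/q² equivalence
holds across batches; a per-batch denominator is available behind
`per_batch_denominator=True` but breaks that exactness and is not the
default.

Weight decay applies to connection weights only — biases never enter the
penalty.

## Optimization

Plain SGD: seeded shuffle each epoch, mini-batches of `batch_size` rows,
update `w ← w − η·∇J`. Backpropagation is hand-written and verified against
central finite differences (relative error < 1e-6 on every weight; measured
~1e-9).

**Inverted dropout** is applied to hidden activations only (never input or
output): each mini-batch draws a fresh mask, survivors are scaled by
1/(1−rate), and inference applies no mask and no scaling. At rate 0 no
random numbers are drawn at all, so a rate of 0 is bit-identical to a
dropout-free code path (asserted against an independent SGD loop with no
mask logic).

**Early stopping**: every `eval_interval` epochs the full cost J is
computed on a held-out set; training stops after `patience` consecutive
non-improving evaluations (patience 0 disables early stopping) or at
`max_epochs`, and the weight snapshot from the best evaluation is returned.
The returned weights reproduce the recorded best cost exactly on
re-evaluation.

**Seeding contract**: one master seed derives the init, shuffle and dropout
streams via `SeedSequence(master).generate_state(3)`. Everything downstream
is bit-reproducible from the master seed.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| hidden layers | 20, 20, 20 | compact reference architecture; enough capacity for descriptor tables of tens of columns |
| learning rate η | 0.1 | see below |
| batch size d | 16 | small-dataset regime; several updates per epoch at m ≈ 100–200 |
| max epochs | 2000 | upper bound; early stopping ends most runs sooner |
| eval interval | 10 epochs | cheap held-out evaluation without dominating runtime |
| patience | 20 evaluations | 200 epochs of grace under dropout noise |
| dropout | 0.1 | mild regularization appropriate to 20-wide layers |
| λ | 1e-4 | weak decay; the q² term has magnitude ~1 |

The fitting layer (`fit_model`, variable selection) standardizes the
activity to zero mean / unit sd of the training set before optimization and
stores the transform in the model (inverted at prediction). q² and r² are
invariant under this joint affine map, so reported statistics are
unchanged; what it buys is scale-freedom of the learning rate — the −q²
gradient is the SSE gradient divided by SST, so without standardization the
effective step size would shrink with the variance of the activity. With
standardized targets η behaves like an ordinary MSE learning rate, and
η = 0.1 trains the reference architecture to q² > 0.99 on clean data within
the epoch budget; η = 0.01 demonstrably under-fits there, which is why the
larger default was adopted.

## Data washing

Order: normalization → outlier removal → correlation pruning. Washing
precedes any model building.

**Normalization**: per-column z-score (population sd) by default, min–max
to [0,1] as an alternative; constant columns are dropped and reported;
parameters are stored for reuse on prediction inputs and are exactly
invertible.

**Outlier removal (3σ / Pauta rule, local)**: the premise is that
structurally similar compounds have similar activity, so the rule is
evaluated on descriptor-space neighbourhoods rather than the whole dataset.
The neighbourhood of a compound is every other compound within radius r,
where r is the `radius_quantile` (default 0.10) quantile of all pairwise
Euclidean distances — a scale-free choice that adapts to descriptor
dimensionality. A compound is flagged iff

1. its neighbourhood has **strictly more than** `min_neighbors` (default
   10) members — below that, a 3σ call is not statistically meaningful and
   the compound is left alone; and
2. its activity deviates from the neighbourhood mean by more than `sigma`
   (default 3) neighbourhood standard deviations. A zero local sd with a
   nonzero deviation still flags.

Detection runs once on the original table — removals never cascade. A
dataset-global mode (`mode="global"`) is available behind a flag for
comparison. Under pure Gaussian activities with dense neighbourhoods, the
measured flag rate is ~0.2–0.3% (two-sided 3σ normal mass is 0.27%).

**Correlation pruning**: greedy double loop over the Pearson correlation
matrix — for i = 1..n, for j = i+1..n (skipping deleted columns), delete
column j when |corr(b_i, b_j)| > threshold (default 0.95). Earlier columns
always win; two nearly anti-correlated descriptors are treated as redundant
too (absolute value). The output has no remaining pair above the threshold
and the operation is idempotent. Note the threshold is a genuinely free
parameter: reasonable values for descriptor exports are 0.90–0.99.

**PCA** (optional alternative reduction): center columns, covariance
(ddof 1), `eigh` eigendecomposition, sort descending, project onto the top
p eigenvectors. Retained as an option; in practice the descriptor
correlation is often so high that choosing p is awkward, which is why
pairwise pruning is the default route.

**Similarity diagnostics**: `euclidean_nearest` (descriptor space) and
`tanimoto_nearest` (binary fingerprints, TC = |A∩B|/|A∪B|, defined 0 with a
warning when both fingerprints are empty) report the most similar training
compound. A large distance / low TC marks a prediction as outside the
well-sampled region (applicability domain); `predict_with_applicability`
attaches the distance to each prediction.

## Sphere-exclusion splitting

Rational train/test division: the guarantee the scheme exists for is that
**every test compound lies within the sphere radius of at least one
training compound**, so external validation measures interpolation, not
extrapolation. Several sphere-exclusion variants exist; the one implemented
is a deterministic max–min sweep:

1. first center = compound with the highest activity (ties →
   lexicographically smallest ID), so the covered range includes the top of
   the activity scale;
2. the current center joins the **training** set; all unassigned compounds
   within radius r of it join the **test** set;
3. the next center is the unassigned compound farthest from all existing
   centers (max–min distance; ties → smallest ID);
4. repeat until all compounds are assigned.

The radius is tuned by bisection (40 iterations over [0, max pairwise
distance]) so the achieved test fraction is closest to the requested
target; if the target is unreachable the closest split is returned with a
warning. The coverage invariant holds by construction and is re-asserted in
tests. There is no hidden randomness: identical inputs give identical
splits. The split is recomputed whenever the descriptor subset changes,
because the distances that define it change with the space.

## Variable selection

A wrapper search over descriptor subsets of size k: for each subset,
restrict the table, **re-run the sphere-exclusion split in the subset's own
descriptor space**, train a fresh network with early stopping (the external
test set doubles as the early-stopping evaluation set), and score the model
by `min(q2_train, r2_test)` — a subset must perform both internally and
externally, and the minimum aggregates the two conservatively (a sum score
is available behind a flag). Ties break by higher r2_test, then
lexicographic subset order.

Exhaustive search enumerates all C(K, k) subsets; random search draws
distinct subsets without replacement up to `max_evals`. Each subset's
training seed is derived from the master seed plus the subset's column
indices, so serial and joblib-parallel evaluation are bit-identical and the
whole run reproduces from one seed. A model is *accepted* when q2_train ≥
0.60 and r2_test ≥ 0.55 (both inclusive, both configurable); if nothing
clears the bar the best subset is still returned, flagged unaccepted.

## Synthetic data generator

The generator emulates the statistical shape of a descriptor export, not
chemistry: block-equicorrelated Gaussian descriptors (shared-factor
construction `sqrt(ρ)·f + sqrt(1−ρ)·ε`, giving exactly ρ within-block
population correlation), a small active subset driving the activity through
a linear or tanh link with coefficients of magnitude 1–2 and random sign,
Gaussian assay noise, optional ×1000 column rescaling to exercise
normalization, and planted activity outliers displaced by a requested
multiple of the local activity sd — in dense descriptor regions (so the
washer should find them) or in a remote corner of the space (so the
neighbour-count rule should protect them). The full generative record
(coefficients, outlier IDs, block membership, scales) is returned, making
every downstream operation testable against ground truth.

What passing tests on this generator shows: the machinery recovers planted
structure under controlled correlation, noise and contamination. What it
does not show: performance on real descriptor distributions (heavy tails,
discrete counts, nonlinear descriptor–descriptor dependence) or real
activity cliffs; nothing here models molecular graphs.

## Benchmark sizes used by tests and the acceptance script

Training benchmarks use 200 compounds × 5 descriptors with the default
network; the variable-selection benchmark uses 120 × 10 with a reduced
network (one hidden layer of 10, 200 epochs, patience 10) across the 45
exhaustive k=2 subsets and 10 seeds — subset *ranking* needs a fit good
enough to separate signal from noise columns, not a polished model, and the
reduced setting recovers the planted pair in 10/10 seeds. The Pauta
false-positive rate is measured over 50 replicates of 80 clean compounds.

## Numerical notes and edge cases

- q² requires non-constant observed activities (validation error
  otherwise); r² (squared Pearson) additionally degenerates to 0 with a
  warning when predictions are constant. An `about_train_mean` r² variant
  (coefficient of determination about the training mean) is available.
- Model files are JSON with every float serialized as its full `repr`
  string: save→load is bit-exact and the file is diffable. A version tag is
  checked on load; CSV parsing goes through numpy's correctly-rounded
  string→float conversion so table round trips are bit-exact as well.
- Duplicate compounds sit at distance 0: sphere exclusion assigns the
  duplicate of a center to the test set for any radius ≥ 0; the nearest-
  neighbour diagnostics exclude the query itself.
- NaN/Inf in a gradient or training cost aborts with a `TrainingError`
  carrying learning-rate guidance; washing rejects tables with missing
  values unless mean-imputation is explicitly enabled.

## Known limitations

- q² here is the fitted-set statistic (no leave-one-out resampling), and
  r² is the plain squared Pearson correlation on the external test set; the
  full Golbraikh–Tropsha acceptability battery (slope/intercept criteria)
  is not implemented.
- The sphere-exclusion variant is one of several in use; set sizes obtained
  for a given radius differ between variants.
- Exhaustive selection is O(C(K,k)) model fits; beyond small K choose the
  random strategy and a budget.
- No momentum/Adam-class optimizers, no GPU path; the implementation
  targets descriptor tables of hundreds of compounds, not millions.
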