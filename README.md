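# qsarnet

Deep-network QSAR regression with a q²-based training cost.

`qsarnet` is for modelers who have a table of precomputed molecular
descriptors (MOE/CDK-style exports: one row per compound, one numeric
column per descriptor) and a measured activity (pIC50, LAC50, permeability)
and want a reproducible, externally validated regression model. It covers
the full workflow: data washing, rational train/test splitting, network
training, scoring, variable selection, and prediction with an
applicability-domain diagnostic — as a Python library and a `qsarnet` CLI.

## The method

The regressor is a fully connected feed-forward network (tanh hidden
layers, linear output) trained by mini-batch SGD against the cost

    J(W, λ) = −q² + (λ/2) Σ (W^l_ij)²,   q² = 1 − Σ(h(x_i) − y_i)² / Σ(y_i − ȳ)²

Because Σ(y−ȳ)² is a constant of the training set, minimizing J is exactly
equivalent to maximizing the correlation coefficient q², while the λ-term
(L2 weight decay on connection weights, never biases) suppresses
overfitting. Inverted dropout on hidden layers and early stopping on
held-out cost further regularize training. Around the network:

- **Washing** — z-score/min-max normalization; local 3σ (Pauta) activity-
  outlier removal, where a compound is flagged only if its descriptor-space
  neighbourhood has more than 10 members and its activity deviates more
  than 3 local standard deviations from the neighbourhood mean; greedy
  Pearson-correlation pruning of redundant descriptors; optional PCA.
- **Sphere-exclusion splitting** — a deterministic rational partition that
  guarantees every test compound lies within a tuned radius of some
  training compound, recomputed whenever the descriptor set changes.
- **Variable selection** — exhaustive or random search over descriptor
  subsets of size k, re-splitting and retraining per subset, ranked by
  min(q²_train, r²_test); models are accepted when q²_train ≥ 0.60 and
  r²_test ≥ 0.55.
- **Synthetic fixtures** — a generator of descriptor tables with known
  correlation blocks, active subsets, noise and planted outliers, so the
  whole stack is testable without any external data.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

Simulate a 200-compound table with 30 descriptors (two blocks of five
nearly duplicate columns, four truly active descriptors, two planted
activity outliers), wash it, split it, and train:

```python
import qsarnet as q
from qsarnet.pipeline import fit_model

spec = q.SyntheticSpec(m=200, k=30, blocks=(5, 5), rho=0.98,
                       active=(0, 5, 10, 11), noise_sd=0.3,
                       n_outliers=2, seed=17)
table, truth = q.generate(spec)
washed, norm, report = q.wash_table(table, q.RunConfig(seed=17))
print("outliers removed:", [o.compound_id for o in report.removed_outliers])
print("descriptors:", table.n, "->", washed.n)
split = q.sphere_exclusion_split(washed, 0.2)
print("split:", len(split.train_ids), "train /", len(split.test_ids),
      "test, radius %.3f" % split.radius)
model, state, rep = fit_model(washed, split, norm, q.RunConfig(seed=17))
print(rep.summary())
```

Output:

```
outliers removed: ['C0132', 'C0152', 'C0178']
descriptors: 30 -> 22
split: 158 train / 39 test, radius 4.182
q2_train=0.9432 q2_test=0.9200 r2_test=0.9501 n_train=158 n_test=39 stop_epoch=40
```

The washer caught both planted outliers (C0132, C0152, plus one chance
3σ excursion), pruned the 8 redundant block columns (30 → 22), and the
trained model clears the acceptance bar (q²_train ≥ 0.60, r²_test ≥ 0.55)
comfortably: the fitted-set correlation coefficient is 0.94 and the
squared Pearson correlation on the 39 held-out compounds is 0.95. The same
run from the shell:

```sh
qsarnet pipeline --simulate --seed 17 --outdir run/
qsarnet predict --model run/model.json --in new_compounds.csv --out preds.csv
```

All stages are driven by an XML parameter file (`--config run.xml`):

```xml
<javadl>
  <network>
    <hidden_layers>20,20,20</hidden_layers>
    <lambda>1e-4</lambda>
    <dropout>0.1</dropout>
  </network>
  <wash><corr_threshold>0.95</corr_threshold></wash>
  <split><test_fraction>0.2</test_fraction></split>
  <seed>17</seed>
</javadl>
```

Absent elements take documented defaults; unknown element names are hard
errors, so a typo cannot silently corrupt an experiment.

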