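# isingml

Quantum-annealer-inspired classification implemented classically: a
multinomial classifier whose training objective is encoded as an Ising
Hamiltonian over binary weights, solved with annealing-family heuristics,
plus a classification RBM and a leakage-free evaluation harness for
small-sample, high-dimensional (multi-omics-like) data.

## What it does

- **Encoding** (`isingml.encoder`): the softmax negative log likelihood
  with K−1 weight vectors of length M is Taylor-expanded to second order
  around zero weights, producing an Ising problem over D = M·(K−1) spins
  (per-class linear blocks, within-class and between-class couplings).
  Includes capacity arithmetic (`max_features`, `logical_variable_count`),
  coefficient rescaling into [−1, 1], and JSON / plain-text problem export.
- **Solvers** (`isingml.solvers`): simulated annealing (Metropolis sweeps,
  linear inverse-temperature schedule, β₀ = 0.01, tunable β_f, 1,000 sweeps
  and 1,000 reads by default), a random sampler, a fields-only analytic
  baseline, and an exhaustive enumerator used as a test oracle (D ≤ 20).
- **Model** (`isingml.model`): the 20 lowest-energy spin configurations are
  greedily averaged whenever the average strictly improves the exact
  training NLL, yielding weights in [−1, 1]; softmax probabilities,
  prediction, and 10-fold cross-validated selection of β_f over
  {0.03, 0.1, 0.3, 1, 3}.
- **RBM** (`isingml.rbm`): classification RBM with one-hot label units
  joined to the visible layer, CD-1 training (batch 32, binarized hidden
  units), exact free-energy scoring of each candidate label.
- **Evaluation** (`isingml.evaluation`): repeated stratified 80/20 splits,
  train-fitted z-scoring and PCA with test projection, accuracy / balanced
  accuracy / AUC / F1, pairwise Wilcoxon signed-rank tests with Bonferroni
  correction, training-fraction sweeps against a fixed held-out test set,
  overfitting gaps, and weight-based feature importance.
- **Synthetic data** (`isingml.synthetic`): seeded generators for
  block-correlated, mean-shifted feature matrices in configurable n ≪ M
  regimes, so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic dataset
isingml simulate --spec spec.yaml --out toy        # writes toy_X.csv, toy_y.csv

# encode it as an Ising problem and solve
isingml encode --data toy_X.csv --labels toy_y.csv --out problem.json
isingml solve --problem problem.json --solver sa --beta-final 3 --reads 1000 --seed 1

# train a classifier (SA tunes beta_f by 10-fold CV)
isingml train --data toy_X.csv --labels toy_y.csv --solver sa --seed 1 --out model.json

# full repeated-split evaluation and training-fraction sweep
isingml evaluate --data toy_X.csv --labels toy_y.csv \
    --classifiers sa,random,field,rbm --n-splits 100 --pcs 44 --seed 1 --out results/
isingml sweep --data toy_X.csv --labels toy_y.csv \
    --fractions 0.95,0.8,0.6,0.4,0.2 --replicates 50 --seed 1 --out sweep.csv
```

A `spec.yaml` for `simulate` mirrors `SyntheticSpec`, e.g.:

```yaml
n_per_class: [100, 100]
n_features: 44
n_informative: 6
effect_size: 1.0
within_block_correlation: 0.3
block_sizes: [22, 22]
seed: 7
```

## Notes

- All randomness flows through explicit integer seeds
  (`numpy.random.SeedSequence` spawning); identical configurations produce
  byte-identical reports.
- Solvers operate on the [−1, 1]-rescaled problem so the β grid behaves
  consistently across datasets.
- The last listed class is the softmax pivot (its weight vector is fixed
  at zero); relabeling therefore changes the encoding.
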