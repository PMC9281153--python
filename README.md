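# scdlc

An LSTM-based classifier for large-sample single-cell RNA-seq count
data, with BW-ratio gene selection, a Splatter-style count simulator,
and reproducible simulation-study harnesses.

## Who this is for

Computational biologists who want a supervised, distribution-free cell
classifier for genes × cells count matrices — assigning cell types,
conditions or donor groups to new cells from labelled training data —
and methodologists who want a fully seeded sandbox for studying how such
a classifier behaves as sample size, differential-expression strength
and dropout (excess zeros) vary.

## The method

1. **Gene selection.** Genes are ranked on the training set by the BW
   ratio of between-class to total sum of squares,

       BW(j) = Σₖ Σᵢ (x̄ₖ.ⱼ − x̄..ⱼ)² / Σₖ Σᵢ (xₖᵢⱼ − x̄..ⱼ)²,

   with x̄..ⱼ the unweighted mean of the K class means; the top p
   (default 100) genes become the classifier's inputs.
2. **Classifier (scDLC).** A first fully connected ReLU layer maps the
   selected expression vector to a sequence of p timesteps × 64
   features; two stacked LSTM sublayers (hidden size 64, gates
   f/i/o with a persistent cell state C) consume the sequence; a second
   fully connected layer and a softmax turn the final hidden state into
   class probabilities.
3. **Training.** Cross-entropy loss, mini-batch gradient descent
   (batch 11), global-norm gradient clipping at 5, dropout keep
   probability 0.3 on LSTM outputs, and a learning rate decaying
   exponentially from 0.005 to 0.001 over the run:
   η(s) = max_lr·e^(−r·s), r = log(max_lr/min_lr)/total_steps.
   Backpropagation through time is implemented analytically in NumPy and
   validated against finite differences.
4. **Evaluation.** Misclassification rate and (macro one-vs-rest,
   tie-corrected Mann-Whitney) AUC over stratified train/test splits.

The built-in simulator draws gamma gene means, log-normal DE fold
changes with random direction, log-normal library sizes, Poisson counts
and a Bernoulli excess-zero mask — the quantities (K, n, g, DE, p_zero)
the simulation studies vary. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

```python
from scdlc import (SimulationConfig, simulate_counts, split_train_test,
                   select_top_genes, TrainConfig, train_model,
                   evaluate_model)

cfg = SimulationConfig(n_classes=2, n_per_class=(400, 400), n_genes=100,
                       de_proportion=0.7, p_zero=0.1, seed=11)
matrix, labels = simulate_counts(cfg)
(train_m, train_l), (test_m, test_l) = split_train_test(matrix, labels,
                                                        n_train=400, seed=2)
ranking = select_top_genes(train_m, train_l, p=100)
params, report = train_model(train_m, train_l, ranking,
                             TrainConfig(epochs=30, seed=5))
result = evaluate_model(params, test_m, test_l, ranking)
print(f"train accuracy      {report.final_train_accuracy:.3f}")
print(f"test misclassification {result.misclassification_rate:.3f}")
print(f"test macro AUC      {result.auc_macro:.3f}")
```

prints

```
train accuracy      0.998
test misclassification 0.072
test macro AUC      0.974
```

800 cells are simulated in two classes with 70 of 100 genes
differentially expressed and 10% excess zeros; half train the model,
half are held out. Training reaches near-perfect accuracy, and on the
held-out cells the classifier misassigns 7.2% and ranks a random
correct-class cell above a random other-class cell 97.4% of the time.

The same pipeline is available from the shell:

```
scdlc simulate -k 2 -n 800 -g 100 --de 0.7 --p-zero 0.1 --seed 11 --out data/
scdlc select --counts data/counts.tsv --labels data/labels.tsv --top 100 --out rank
scdlc train --counts data/counts.tsv --labels data/labels.tsv \
            --ranking rank.json --seed 5 --out model.npz
scdlc evaluate --model model.npz --counts data/counts.tsv \
               --labels data/labels.tsv --ranking rank.json
scdlc run --config pipeline.yaml --seed 1 --out results/   # end to end
```

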