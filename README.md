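# alleracc

Alignment-free prediction of protein allergenicity from sequence alone.

Allergens are proteins that trigger IgE-mediated hypersensitivity.
Sequence-similarity screens (the classic "six consecutive identical
residues or >35 % identity" rules) miss allergens with low homology to
known ones, so this package takes the alignment-free route: every protein
is described by per-residue physico-chemical scores, compressed to a
fixed-length vector, and classified by conventional machine-learning
models — the approach behind the AllerTOP family of predictors, here with
a benchmarked suite of eight classifiers including an LSTM network.

## Method

1. **E-descriptor encoding.** Each of the 20 canonical amino acids is
   represented by five orthogonal principal-component scores of 237
   physico-chemical properties (E1 hydrophilicity, E2 size, E3 helix
   propensity, E4 abundance/dispersion, E5 β-strand propensity), so a
   protein of length *n* becomes an *n* × 5 matrix *E*.
2. **Auto/cross-covariance (ACC) transform.** Variable-length matrices are
   reduced to a fixed 125-vector of lagged products,

   &nbsp;&nbsp;&nbsp;&nbsp;AC<sub>jkl</sub> = (1/(n−l)) Σ<sub>i=1..n−l</sub> E<sub>j,i</sub> · E<sub>k,i+l</sub>,&nbsp;&nbsp; j,k ∈ {1..5}, lag l ∈ {1..5},

   with j = k the auto-covariance and j ≠ k the cross-covariance terms.
   Features are named `ACjkl` (`AC111` … `AC555`).
3. **Classification.** Eight methods behind one seeded train/predict
   contract: Gaussian naive Bayes, radius-neighbours, bagging, AdaBoost,
   linear and quadratic discriminant analysis, extra-trees, and a
   four-layer LSTM network (LSTM → dense relu → dense relu → softmax(2),
   categorical cross-entropy, RMSProp) implemented in numpy.
4. **Evaluation.** One stratified 80:20 split shared by all methods;
   accuracy, precision TP/(TP+FP), recall TP/(TP+FN), F1 (harmonic mean)
   and trapezoidal ROC/AUC with the allergen class positive.

A synthetic-data module generates balanced two-class sequence datasets
with a tunable composition separation (0 = identical classes), so the full
pipeline is testable — including a null calibration that detects label
leakage — without any external download.

## Worked example

```sh
python examples/benchmark_classifiers.py
```

generates 300 synthetic sequences per class (lengths 50–500, separation
0.12, seed 5), featurizes them, and benchmarks all eight methods on one
stratified 80:20 split:

```
method             train_acc%  test_acc%  precision  recall    F1    AUC
gaussian_nb             99.58      99.17       0.98    1.00  0.99  0.999
radius_neighbors        99.38      96.67       1.00    0.93  0.97  0.942
bagging                100.00      95.00       0.94    0.97  0.95  0.996
adaboost               100.00      99.17       0.98    1.00  0.99  1.000
lda                    100.00      99.17       0.98    1.00  0.99  0.994
qda                     99.58      99.17       0.98    1.00  0.99  1.000
extra_trees            100.00      99.17       0.98    1.00  0.99  1.000
lstm                   100.00      99.17       0.98    1.00  0.99  0.990
best method by AUC: adaboost
```

Test accuracy is the held-out fraction correct (percent); precision the
fraction of allergen calls that are allergens; recall the fraction of true
allergens recovered; AUC the probability a random allergen outranks a
random non-allergen.  The default synthetic separation makes the task
easy on purpose — it verifies signal propagation, not difficulty.

The same pipeline is scriptable from the shell
(`alleracc simulate | featurize | train | benchmark | predict`); see
`alleracc --help`.  `examples/` holds one short narrative script per
capability.

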