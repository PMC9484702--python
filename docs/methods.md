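# Methods

## Sequence ingestion and validation

Sequences are read from multi-record FASTA (wrapped lines joined, ids
taken from the header up to the first whitespace, uppercased, `*` stop
characters stripped with a warning).  The canonical alphabet is the 20
standard one-letter codes; ambiguity and non-standard codes (B, J, O, U,
X, Z, gaps) have no descriptor values, so the default policy is strict
rejection, with `drop` (exclude the record) and `map_unknown` (remove the
offending letters) available.  Redundancy removal is exact full-sequence
identity, case-insensitive, keeping the first occurrence; duplicates with
conflicting class labels are ambiguous ground truth and raise.  Exact
identity was chosen over similarity clustering because it is deterministic
and assumption-free; users wanting homology-aware reduction should apply
it upstream.

## E-descriptors

The 20 × 5 E-descriptor table (five orthogonal principal-component scores
summarizing 237 physico-chemical properties per amino acid: E1
hydrophilicity, E2 size, E3 helix propensity, E4 abundance/dispersion, E5
β-strand propensity) ships as a tab-separated asset transcribed once from
the primary source (Venkatarajan & Braun 2001).  Its sha256 was recorded
at transcription time and is verified on every load: a corrupted asset
fails hard rather than silently altering every downstream feature.
User-supplied tables (e.g. z-scales) are accepted through the same format.
Descriptor values are used as published, with no standardization before
the ACC step.

## ACC featurization

For descriptor pair (j, k) and lag l, the default dialect computes
`AC_jkl = 1/(n−l) · Σ_{i=1..n−l} E_{j,i} · E_{k,i+l}` — the raw lagged
product sum, no mean-centering, normalized by the number of summands.
This follows the AllerTOP-v2 lineage of ACC use on E-descriptors.  Because
the precise normalization in that line of work is not always recoverable
from publications, two alternative dialects are exposed for sensitivity
analysis (`uncentered_n`: divide by n; `centered`: subtract each
descriptor's sequence mean first) rather than hiding the ambiguity.

Features are ordered lexicographically in (j, k, l) and named `ACjkl`, so
persisted matrices and models are auditable and portable.  The transform
requires n ≥ L + 1 (each lag needs at least one summand); shorter
sequences error by default or are dropped with a warning under the `drop`
policy.  The implementation is a per-lag matrix product; tests verify it
against an independently coded quadruple-loop oracle to 1e−10, plus the
analytic closed forms (homopolymers give AC_jkl = E_j·E_k independent of
lag and length; reversal swaps j and k; scaling the table by c scales
every feature by c²).

## Classifiers

Seven classical methods are scikit-learn estimators behind a uniform
spec/train/predict contract; every spec carries an explicit seed and the
pinned hyperparameter defaults are echoed into reports:

| kind | defaults | note |
|---|---|---|
| gaussian_nb | — | |
| radius_neighbors | radius = median pairwise training distance | empty neighbourhoods get the majority training label |
| bagging | 200 trees | |
| adaboost | 100 rounds | |
| lda | — | |
| qda | reg_param 1e−3 | ACC features are collinear; the unregularized class covariance can be rank-deficient |
| extra_trees | 200 trees | |
| lstm | see below | |

The LSTM is a compact numpy implementation: exactly four layers — an LSTM
layer, two dense layers, and a 2-unit softmax — with relu as the three
hidden activations (in the LSTM cell, relu serves as the candidate and
cell-output activation; the gates keep their logistic sigmoids), trained
with categorical cross-entropy under RMSProp (lr 1e−3, ρ 0.9), global
gradient-norm clipping at 5, Glorot initialization, forget-gate bias 1.
Defaults: hidden sizes 64/32/16, 40 epochs, batch 32.  A 125-vector
enters the recurrent layer reshaped to (5 timesteps, 25 channels): the lag
is the only sequential axis ACC preserves, so it is the natural time axis;
a flat (d, 1) layout is available by config for comparison.  Features are
standardized per column (fit on the training split) inside the LSTM
estimator only — raw ACC values have magnitude ~1e−2, which stalls
RMSProp at this learning rate; the classical estimators consume raw
features.  Training is single-threaded pure numpy and bit-reproducible
for a fixed seed.

Class convention throughout: allergen = positive = 1, one-hot order
(non_allergen, allergen), hard calls at score ≥ 0.5 with ties going to
allergen (for a safety screen, the conservative direction).

Model artifacts are directories holding a JSON metadata document (format
version, spec, feature names, seeds, pinned defaults, training summary)
plus the joblib-serialized estimator; loads refuse other format versions
unless forced, and prediction refuses feature matrices whose column names
differ from those seen at training.

## Evaluation

A single seeded stratified 80:20 split (scikit-learn `train_test_split`)
is shared by all methods in a benchmark; stratification keeps per-class
balance within one sample (a flag disables it).  Metrics: accuracy
(TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN), F1 the harmonic
mean of precision and recall; undefined ratios are reported as 0 and
flagged rather than raised.  ROC curves sweep the unique score thresholds
descending with ties grouped, so the trapezoidal AUC equals the
tie-corrected Mann–Whitney concordance probability (tested equivalence).
Reports serialize to JSON at full precision with all seeds and defaults,
and render as a text table with percent accuracies and two-decimal
fractions.

## Synthetic data

The generator emulates a balanced curated corpus: per class,
`n_per_class` sequences with lengths uniform on (50, 500) — typical
protein lengths, fast to featurize — and residues drawn i.i.d. from a
class composition built from Swiss-Prot-like background frequencies by
moving `separation` total probability mass onto a class-enriched residue
triple (allergen: A/K/E; non-allergen: L/S/G) and off the other class's
triple, then renormalizing.  The triples use abundant residues so
realistic separations cannot drive any frequency negative (infeasible
values raise with guidance).  An i.i.d. model was chosen deliberately:
the expectation of every ACC feature is then the product of class-mean
descriptors, so signal propagation, monotonicity in `separation`, and
null behaviour are analyzable.  An optional motif inserted into allergen
sequences adds positional (lag-sensitive) signal.

The default separation 0.12 was fixed once, by the design rule that a
plain linear model on raw residue composition must separate the classes
with AUC well above 0.9 — making the downstream bound (tree ensembles and
the LSTM reaching ≥ 0.9 on ACC features) a test of the pipeline, not of
classifier ingenuity.  At separation 0 the two classes are generated from
one distribution; `null_calibration` runs the entire
generate→featurize→split→train→score pipeline repeatedly and checks mean
test AUC sits at chance — a leakage detector for the whole codebase.

What passing these tests does **not** show: real allergens differ from
non-allergens by homology structure, domain architecture and epitopes,
not by i.i.d. composition shifts.  Synthetic results validate the
machinery (encoding, featurization, training, evaluation, determinism),
not biological performance; benchmarking on a curated corpus is the
optional replication harness's job.

## Numerical and design notes

* The F1 reported everywhere is the standard precision-based harmonic
  mean; published benchmark tables of this design are internally
  consistent with it to two decimals (verified for five
  precision/recall/F1 rows in the acceptance suite).
* Feature tables round-trip bit-exactly through TSV (`%.17g` writing,
  round-trip float parsing).
* Problem sizes in tests and the acceptance script (≤ 1,000 sequences per
  class, ≤ 50 LSTM epochs, 5 null repetitions at 500 per class) were
  chosen to exercise every claim at statistically meaningful scale while
  keeping a full run in the minutes range on one CPU.
* Known limitations: no similarity-based redundancy reduction; no k-fold
  cross-validation (single split by design); the LSTM is intentionally
  small and has no dropout or early stopping; no GPU path.
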