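# Methods

This package classifies immune repertoires — sets of CDR3 amino-acid
sequences with clone counts — into positive/negative phenotype classes. It
implements two methods with deliberately different failure modes, plus a
benchmark protocol that measures how each degrades as the training cohort
shrinks, and a synthetic generator that plants either kind of signal.

## Repertoire representation and I/O

A repertoire sample (`RepertoireSample`) is a canonical pair of arrays:
unique CDR3 amino-acid sequences (uppercase, 20-letter alphabet
`ACDEFGHIKLMNPQRSTVWY`) and positive integer clone counts. Duplicate
sequences are merged on construction and sequences are kept sorted, so two
samples with the same content compare equal regardless of input order.
Samples carry a label (`positive`, `negative`, or `unknown`), an optional
cohort tag, and the number of input records dropped during parsing.

`io.py` reads per-sample TSV files in two dialects: a minimal
`sequence`/`count` layout and an AIRR-style layout
(`junction_aa`/`cdr3_amino_acid` + `duplicate_count`/`templates`). Rows with
invalid sequences or non-positive counts are dropped and counted, never
silently altered. A metadata TSV maps sample identifiers to labels and
cohorts.

## k-mer featurization

Each sample becomes a fixed-length vector of k-mer frequencies over a
21-letter alphabet: the 20 amino acids plus a single edge symbol `#`
prepended and appended to every sequence. For window width `k`, every
sequence of length `L` contributes `L + 2 - k + 1` windows, each weighted by
the clone count of its sequence (or by 1 under `unique` weighting). Windows
are indexed lexicographically with `#` before `A` (base-21 positional code),
and the resulting count vector is normalized to sum to 1. For `k = 3` the
feature space has `21^3 = 9,261` dimensions; `pattern_count(k,
include_edge=False)` counts the `20^k` edge-free patterns.

The implementation vectorizes over an entire sample by joining the padded
sequences, computing rolling base-21 window codes, masking windows that
straddle sequence boundaries, and accumulating weighted counts with
`numpy.bincount`. Tests verify it against a direct per-window brute-force
oracle, including under randomized inputs.

## Classifier with resampling augmentation ("MotifBoost" arm)

`model.py` fits a gradient-boosted decision tree (LightGBM) on the k-mer
vectors. Before featurization the training set is optionally augmented:
each sample is resampled `copies_per_sample` times by drawing
`floor(fraction * total_count)` reads from its count-weighted multinomial
(defaults: fraction 0.5, 5 copies). Augmented copies inherit their source's
label and are tracked in a group map.

Hyperparameters are selected by seeded random search over learning rate,
leaf count, `min_data_in_leaf`, feature/bagging fractions, and L1/L2
penalties, scored by grouped stratified cross-validation AUC
(`StratifiedGroupKFold`), where a sample and its augmented copies always
land in the same fold — augmentation can therefore never leak across the
CV split. Each fold's LightGBM dataset is binned once and reused across all
search trials, which dominates the fit cost otherwise. Boosting uses a
300-round cap with early stopping (patience 10, minimum delta 5e-4),
`max_bin=31`, a single thread, and deterministic mode; the final model is
refit on all training data with the winning parameters and the mean
early-stopped round count from CV. A logistic-regression classifier on the
same features is available as a comparison arm. All randomness derives from
a single integer seed via SHA-256 (`_seeds.py`), so fits are reproducible.

## Burden-test baseline (Emerson-style)

`burden.py` implements the classical public-clone burden approach. For each
distinct sequence in a labeled cohort, a presence-based 2x2 table (sample
has / lacks the sequence x positive / negative) is scored with a one-sided
Fisher exact test, computed as the hypergeometric upper tail
`sf(a - 1, total, a + c, a + b)`; p-values are memoized per distinct table.
Sequences with `p <= threshold` form the associated set. Each sample's
burden is `(x, n)`: how many of its unique sequences are associated, out of
`n` unique sequences.

Per class, burdens are modeled beta-binomially. Parameters start at the
method-of-moments estimate and are refined by Newton ascent on the exact
log-likelihood with step-halving (falling back to gradient ascent when the
Hessian step is not an ascent direction); zero-variance burdens fall back
to a plain binomial with a clamped rate. A sample's score is the
log-likelihood ratio of the positive versus negative class model. The
p-value threshold is chosen from a fixed grid
(1e-5 ... 1e-1) by stratified CV AUC, ties resolved toward the smallest
threshold, then the model is refit on the full cohort. The whole pipeline
is deterministic given its seed — bitwise-identical scores across repeated
fits.

## Evaluation and the data-efficiency benchmark

`evaluation.py` provides ROC AUC (verified against a brute-force pairwise
concordance oracle in tests), label-stratified cohort subsampling
(rounded half-away-from-zero, clamped so both classes survive), and read-
depth subsampling via the multivariate hypergeometric distribution.

`run_benchmark` takes any set of methods implementing
`fit_score(train, test, seed)`, a training pool, a disjoint test set, a list
of training-cohort sizes, and a trial count. For each (method, size, trial)
it derives an independent seed from the master seed, subsamples the pool
with label stratification, fits, scores the fixed test set, and records the
AUC; failures are recorded as NaN with the error message rather than
aborting the run. Reports summarize median/quartiles per condition and can
render box plots. Additional diagnostics: projecting 2-D per-sample
statistics onto an axis and scanning axis angles for the best-separating
slope, and Spearman correlation between two methods' normalized score
profiles on common samples.

## Synthetic repertoire generator

`simulate.py` draws i.i.d. uniform amino-acid sequences with lengths
uniform on [8, 20] and Zipf(1.5) clone counts capped at 10^4, split into
equal positive/negative cohorts. Two independent, composable signal
channels mirror the two methods' assumptions:

- **Public-clone channel**: a fixed panel of clones generated once per
  dataset, each included in a sample with class-dependent probability
  (defaults: 50 clones, 0.8 in positives vs 0.05 in negatives). This is the
  signal a burden test is built to find.
- **Motif channel**: a 3-mer written into a class-dependent fraction of a
  sample's sequences at a random position (default motif `ASS`, rates 0.02
  vs 0.0). This diffuse signal is invisible to presence-based burden tests
  at small cohort sizes but visible to k-mer features.

With both rates equal (or absent) the generator is an exact null. All
generation is reproducible from the spec's single seed, and specs
round-trip through YAML for the CLI.

## Scale choices in tests and the acceptance script

Benchmark-style checks in this repository run on synthetic cohorts sized
for a single CPU (e.g., 100 samples x 1000 records for motif-effect runs;
260 x 500 for cohort-size breakdown runs). These are desk-scale stand-ins
for population-scale cohorts: large enough that the planted effects are
well inside each method's operating range, small enough to run in minutes.
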