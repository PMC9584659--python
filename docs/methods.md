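# Methods

## Problem setting

Given a labelled matrix of n samples × q features (expression values;
n in the tens, q in the thousands, c ≥ 2 classes), find a small feature
subset that classifies the samples well.  The package implements a
two-stage hybrid: a univariate Fisher-score filter reduces the space to
a fixed-size candidate set, and a clonal-selection immune algorithm — an
elitist evolutionary loop over binary subset masks — searches that set
for a minimal high-accuracy subset.

## Stage 1: Fisher filter

The score of feature i is
F_i = Σₖ n_k (u_kⁱ − uⁱ)² / Σₖ n_k (σ_kⁱ)², with class sizes n_k, class
means u_kⁱ, overall mean uⁱ and within-class variances (σ_kⁱ)².

Numerical conventions (the formula alone does not fix them):

* **Population variance** (divide by n_k).  The sum is weighted by n_k,
  and the biased form remains defined for singleton classes, where the
  unbiased estimator is not.
* **Degenerate denominators** are floored at ε = 1e−12 instead of
  returning infinity, keeping scores finite, totally ordered and
  serialisable.  A feature with distinct class means but zero
  within-class spread therefore gets a huge finite score and outranks
  every finite-variance feature; a feature constant everywhere (0/0)
  scores 0.
* **Tie-break at the cut rank**: ascending original index, for
  determinism.

The filter keeps the top `fisher_k` = 200 features by default — a fixed
operating point that balances candidate-set quality against wrapper
cost; with q ≤ `fisher_k` the filter is a pass-through.  Scores are
computed on the full dataset before the wrapper search; the resulting
selection bias (the filter has seen the labels of all samples) is a
property of the two-stage design and is not corrected here.

## Stage 2: evaluator

A candidate mask with p active features is scored by
fitness = ω·E_r + (1 − ω)·p/q, minimised; q is the candidate-space
size.  ω defaults to **0.99**: almost all weight on accuracy, with the
size term breaking ties among equally accurate subsets.  (A commonly
used alternative, ω = 0.9, is reachable through the config; it trades
noticeably more accuracy for sparsity.)

E_r is the misclassification rate of a k-nearest-neighbour classifier
(k = 5, Euclidean distance, majority vote) under stratified 5-fold
cross-validation.  Determinism contract:

* folds derive from the evaluator seed over a canonical sample order
  (sorted sample ids when present), so the estimate is invariant to row
  permutations of the input;
* if any class has fewer members than the fold count the evaluator
  falls back to leave-one-out;
* k is capped at the training-fold size; neighbour ties at the k-th
  distance keep the earlier training sample; vote ties resolve to the
  smallest class label under a fixed total order.
* feature scaling is **off** by default (expression matrices are
  conventionally compared raw); optional z-scoring uses training-fold
  statistics only.

Fold assignment uses scikit-learn's `StratifiedKFold`; the neighbour
vote itself is vectorised over a distance matrix so that the thousands
of masked-subset evaluations per run are fast and the tie rules above
are exact.  Identical masks hit an error-rate cache; caching never
changes results.  The search and the finally reported accuracy use
independently derived fold seeds, so the reported accuracy is not the
value the search optimised against (it remains an internal CV estimate,
not an external validation).

## Stage 2: search loop

Population of N = 10 antibodies, T_max = 50 iterations, select rate
c_r = 0.5, clone factor β = 1, Cauchy threshold η = −0.2.  Per
iteration t:

1. **Schedule.**  δ = 0.5 − t/T_max (mutation threshold, falls to −0.5)
   and θ = t/T_max (fresh-antibody sparsity regulator, rises to 1).
2. **Selection.**  The n = round(c_r·N) lowest-fitness antibodies,
   ties by fewer active genes then insertion order.
3. **Cloning.**  Rank i (1-based) contributes
   max(1, round_half_away(β·N/i)) deep copies — the canonical
   rank-proportional clone rule of clonal-selection algorithms (with
   the defaults: 10, 5, 3, 3, 2 copies).
4. **Conditional lethal mutation.**  Each locus of each clone draws a
   standard-Cauchy variate; loci with draw > δ mutate, so the expected
   mutated fraction 1 − F(δ) grows from ≈0.35 to ≈0.65 across the run.
   While the best fitness improved at the previous iteration (always at
   t = 1), mutation is *lethal*: active mutation loci are deactivated
   and nothing is activated, so gene counts are non-increasing.  On
   stagnation mutation loci bit-flip instead, restoring exploration.
   Antibodies emptied by mutation are repaired by activating one
   uniformly random locus (keeps p ≥ 1 without biasing any feature).
5. **Incremental update.**  N fresh antibodies are generated by the
   Cauchy threshold rule at threshold η + θ — newcomers start ≈56 %
   dense and end ≈29 % dense — then parents, mutated clones and
   newcomers compete and the N fittest survive (ties: fewer genes, then
   earlier origin).  The previous best is in the pool, so the best
   fitness is non-increasing (elitism).

All randomness (initialisation, mutation loci, fresh antibodies,
repairs, fold seeds) derives from one master seed via numpy
`SeedSequence` spawning; a fixed seed gives a bit-identical result.

### Interpretation choices

Where the loop's prose description leaves the mechanism open, this
package fixes it as follows (these are design choices of this
implementation):

* *Lethal-mutation trigger* — "while the best fitness keeps improving"
  is read as: deactivation-only mutation when the best strictly
  improved at the previous iteration, ordinary flips otherwise.  An
  always-lethal variant was evaluated and behaved similarly on the
  synthetic benchmark; the conditional form retains an exploration
  channel on stagnation.
* *θ's mechanism* — realised as the activation threshold η + θ for
  fresh antibodies, making newcomers progressively sparser.
* *Clone counts* — the rank-proportional round(β·N/i) rule.
* *Mutated clones compete with parents* (merge-and-truncate) rather
  than replacing them.

## Synthetic data

`hfia.make_dataset` emulates the target regime: noise features are
i.i.d. Gaussian(0, noise_sd²); each of `n_informative` randomly placed
features has class-k mean k·mean_shift (equal variances).  Defaults —
100 samples, 2000 features, 10 informative, 2 balanced classes, shift
3, unit noise — mirror the shape of public microarray benchmarks
(2000–22283 features, 50–253 samples).  Ground-truth informative
indices are returned so recovery is measurable.

What it does **not** emulate: probe effects, heteroscedastic or
correlated noise, batch structure, class-dependent covariance.  Passing
tests on this generator show the pipeline recovers planted univariate
mean-shift signal; they do not certify behaviour under real microarray
noise.

A caveat the synthetic experiments make visible: with n = 100 and ~2000
noise features, some noise features correlate with the labels by
chance, enter the Fisher top 200, and can genuinely lower the seeded CV
error of a subset; the fitness-optimal subset may therefore contain a
few such features alongside the planted ones.  This is the familiar
selection bias of wrapper methods at small n, not a search failure —
accuracy and reduction targets are met regardless.

## Problem sizes used in the shipped experiments

Unit and property tests run on matrices up to 100 × 2000; the headline
experiment is 20 independent default-parameter runs on the 100 × 2000
planted benchmark (~1 min total on one CPU with the evaluation cache),
and the optimality-gap check enumerates all 2⁸ masks of an 8-feature
surrogate problem.  The 25 public benchmark datasets of the source
literature are deliberately out of scope; nothing is downloaded.

## Known limitations

* Wrapper accuracies are internal CV estimates; no nested CV or
  held-out validation is performed, so reported accuracies are
  optimistic for generalisation.
* The Fisher filter is univariate: features informative only in
  combination can be discarded before the wrapper ever sees them.
* KNN is the only evaluator (by design); no SVM/tree alternatives.
* Binary microarray formats (CEL/SOFT/MTX) are not read; input is
  delimited text.
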