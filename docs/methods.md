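# Methods

## Problem setting

Given a log-scale expression matrix (genes × samples) and a binary
phenotype (affected / control), the package searches for *small sets*
of genes that jointly discriminate the two classes, rather than ranking
genes one at a time. The motivating setting is a brain microarray study
in which several tissue samples (one per brain region) come from each
subject, so samples are not exchangeable: a subject's brain is diseased
or healthy as a whole, and all of its samples are correlated.

## Candidate-pool construction

1. **Probe aggregation.** Probes mapping to the same gene symbol are
   collapsed by their arithmetic mean.
2. **Differential-expression filter.** Per gene, a Welch two-sample
   t-test (unequal variances, two-sided); Benjamini–Hochberg q-values;
   genes with q > 0.1 are dismissed. Genes with zero variance in both
   classes receive p = 1 (logged) instead of raising, so degenerate
   synthetic inputs run through.
3. **Fold-change ranking.** Survivors are ordered by the absolute
   difference of class means on the log scale and truncated to the top
   1,000. The absolute value is a deliberate choice: strongly
   *down*-regulated genes (e.g. somatostatin-like markers) must rank as
   highly as up-regulated ones; a signed sort is available via a flag.
   Ties break by smaller q, then symbol, so rankings are reproducible.

For evaluation workflows the filter is computed per training fold; for
final biomarker ranking it is computed once on all samples — two tracks
with different leakage requirements.

## Grouped, stratified cross-validation

Folds are built over *subjects*, never samples: subjects of each class
are shuffled (seeded) and dealt round-robin to folds, so per-fold class
counts differ by at most one subject, and because each subject
contributes one sample per stratum (brain-region analog), stratum
proportions even out automatically. No algorithm for this assignment is
canonical; greedy round-robin was chosen for transparency. The
invariant that no subject straddles a train/test boundary is asserted
in tests across 100 seeds, and a deliberate-leak canary (ranking genes
on all samples including test subjects) demonstrates the optimism that
grouping prevents.

## The GA/SVM wrapper

A chromosome is a boolean inclusion mask over the candidate pool. Its
fitness is

    fitness = (1 − w)·accuracy + w·(nAll − nSel)/nAll,   w = 0.2

where *accuracy* is the 6-fold internally cross-validated accuracy of a
Gaussian-kernel C-SVC (C = 1, γ = 1/nSel — the classic libsvm defaults)
trained on the selected genes only, and the second term rewards small
sets. Each generation: 160 offspring from roulette-selected parents via
uniform crossover, plus 20 roulette-selected chromosomes copied and
mutated (independent bit flips at rate 0.0015, ≈1.5 bits on a
1,000-gene mask); the best 200 of the pooled 200 + 160 + 20 = 380
survive. The arithmetic of the pool forces mutants to be *extra copies*
rather than in-place edits. After 25 generations the best chromosome's
gene set is returned. Because parents stay in the pool, best fitness is
non-decreasing — asserted per run.

Numerical and design choices:

- The internal CV split is stratified by class, drawn once per run and
  frozen, so fitness values may be cached by mask within a run.
- An empty chromosome scores fitness 0 (logged) rather than raising.
- Roulette selection uses raw fitness (not rank-scaled); all-zero
  fitness degrades to uniform selection.
- Initialization includes each gene independently with probability
  15/nAll (≈15 genes per chromosome); exact-size initialization is
  available via a flag.
- The SVM layer calls scikit-learn's low-level libsvm bindings
  directly, with a `sklearn.svm.SVC` fallback; both paths produce
  identical predictions (asserted in a dedicated dual-route test). The
  bindings avoid per-call estimator overhead, which dominates at the
  ~100-sample, ~15-feature problems the GA evaluates in bulk.

Repeated runs (200 per fold for evaluation, 500 on the whole data for
ranking, thousands for interaction analysis) yield a frequency ranking:
per-gene count of membership in the final sets. Redundant genes split
their counts across runs — a single run tends to include only one
member of a redundant group — which is precisely what makes this
ranking less redundant than univariate ones.

## Baseline rankers

- **Information gain** after supervised discretization by the
  Fayyad–Irani MDL criterion (recursive binary splitting; candidate
  cuts are midpoints between adjacent distinct values; a split is kept
  when the information gain exceeds the MDL coding cost). Genes with no
  accepted cut score 0 bits. The score depends only on the ordering of
  values, so it is invariant under monotone transforms. A fixed
  equal-frequency-binning fallback is available. The MDL discretizer is
  implemented here because no installed library provides it.
- **Random-forest mean decrease accuracy**: trees grown to purity on
  bootstrap samples (entropy criterion, ⌈√m⌉ candidate genes per
  split); per tree, out-of-bag samples are classified before and after
  permuting one gene's values, and the drop in correct classifications
  is averaged over 1,000 trees and 3 repeated forests. Genes a tree
  never splits on are skipped (permuting them cannot change
  predictions). Composed from `DecisionTreeClassifier` because no
  installed forest implementation exposes per-tree OOB permutation
  importance.
- **Rank aggregation**: per gene, rank positions (not scores) are
  averaged across methods; a gene missing from a list counts as that
  list's length + 1; ties break by symbol.

## Gene-pair interaction analysis

Over S final sets, with single counts k_i and joint counts k_ij, the
expected joint count under independence is k'_ij = k_i·k_j/S, and

    importance_jo(i,j) = log(k_ij / k'_ij)

(natural log; only the ordering is used downstream, so the base is
immaterial). Significance: χ² with 1 df on the full 2×2 per-set
presence/absence table — whose (both, both) expectation is exactly
k'_ij — without Yates correction; pairs with k'_ij ≤ 5 are dismissed
*before* BH correction (the standard χ² validity requirement; the
ordering of filter and correction is a documented choice), and
significance is q ≤ 0.05. k_ij = 0 yields importance −∞, ranked last
among under-represented pairs.

Pair quality is measured by 10-fold cross-validated Gaussian-SVM
accuracies of gene i alone, gene j alone and the pair — the same frozen
split for all three fits, so gains are not split-noise artifacts:

    gainMean = acc_ij − (acc_i + acc_j)/2
    gainMin  = acc_ij − max(acc_i, acc_j)

Accumulation curves average these measures over the 3, 6, 9, … most
over- and under-represented significant pairs, and a Welch two-sample
t-test compares gains between the two directions.

## Over-representation analysis

Upper-tail hypergeometric test of the overlap between a selected set
and a reference list within the gene universe (all genes on the
platform; all generated genes for synthetic runs; reference genes
outside the universe are dropped with a logged count). Three states:
*significant* (p < 0.05), *enriched* (p ≥ 0.05 but overlap above its
expectation), *not enriched*. The sweep over ranking slices (best 40,
60, …, 200 genes) reports raw per-cell p-values with no correction
across the grid — a documented caveat of the three-state display.

## Synthetic data generator

Gene value = baseline (7.0, log2 microarray scale)
+ class shift (informative genes; ±effect_size·noise_sd, alternating
sign so both up- and down-regulated markers exist)
+ w·latent (redundancy-block members; w solved from the target pairwise
correlation ρ via w² = ρ/(1−ρ)·(σ²_subject + σ²_noise))
+ subject random intercept (per gene × subject, SD 0.5 by default — the
within-subject correlation of the motivating dataset is not published,
so this is a free choice exposed in the config)
+ iid Gaussian noise (SD 1.0).

Class labels are assigned at the subject level; default design is 28
subjects × 6 strata with a 0.54 affected fraction, echoing a 161-sample
(87/74) six-region study. Helpers plant near-duplicate genes
(probe-level jitter) and synergy pairs in which the class is encoded in
*which of two genes is larger* — each gene marginally weak because both
ride a shared per-sample level, the pair jointly strong.

What the generator does **not** emulate: probe-level effects, batch
effects, heavy-tailed or non-Gaussian noise, platform-specific
intensity distributions, correlated noise beyond the block/subject
structure. Tests passing on this generator show the machinery behaves
as designed under its stated model, not that the selector's biological
findings on any real dataset are correct.

## Mutual-information redundancy profile

Each gene is discretized into 10 equal-frequency bins over all samples
(bin count shrinks for heavily tied genes, logged) and plug-in MI in
bits is computed for all pairs among a ranking's top genes. No MI
estimator is canonical for this profile; binned plug-in with exposed
bin count was chosen for transparency, so absolute MI values are
estimator-dependent and only *between-method orderings* are
interpreted.

## Validation studies and problem sizes

The pre-registered studies in `biomarker_ga.studies` run the whole
stack on generated data at reduced scale (the package's own choice of
desk-scale sizes), with all randomness derived from one seed:

- *Marker recovery*: 500-gene pool, 120 samples, 10 markers at 1.5σ;
  50 GA runs, population 60, 12 generations, per-gene inclusion
  probability kept at the full-scale 15/1000. Expected: ≥7 planted
  markers in the frequency top-20; monotone traces; median final set
  size ≤ 15 (a tail of runs has not fully pruned at 12 generations —
  full pruning needs the 25-generation schedule).
- *Redundancy*: one strong (2σ) marker duplicated five-fold (jitter
  0.05) among 24 moderate markers; 250 runs. Duplicate pairs passing
  the expectation filter are under-represented; the GA top-20 has lower
  mean pairwise MI than the information-gain top-20; a duplicate pair
  shows no minimal accuracy gain.
- *Synergy*: 17 planted synergy pairs with graded separation plus weak
  single markers; focal-pair significance and gain measured at 200
  runs; pair statistics for the accumulation curves pool 600 runs,
  because the expectation filter plus FDR at 200 runs leaves too few
  significant pairs per direction for a sign test across accumulation
  sizes (the full-scale analysis uses 3,000 runs for the same power
  reason). Under-represented pairs arise from substitution between
  competing synergy pairs. The sign test is one-sided — the direction
  (over-represented pairs gain more) is fixed a priori.
- *Statistical control*: independent random gene sets (3,000 × 15 from
  300), effect-free independent-sample data (20 seeds, pooled KS), and
  1,000 random ORA selections hold their nominal error rates. The
  uniformity check uses subject_effect_sd = 0 deliberately: with
  subject random effects the per-sample t-test is miscalibrated, which
  is exactly why folds are grouped by subject.
- *Leakage canary*: on weak-signal data (0.5σ, 400 genes), a ranking
  computed on all samples (test subjects included) must beat the
  leak-free per-fold ranking on apparent test accuracy.

## Known limitations

- The GA is a stochastic search; different seeds give different final
  sets, and all set-level conclusions are therefore statements about
  frequencies over many runs.
- Internal 6-fold CV accuracy on ~100 samples is quantized at roughly
  1/n per fold, so the parsimony term only separates chromosomes whose
  internal accuracy ties; sets shrink slowly once accuracy saturates.
- χ² pair statistics need expected joint counts above 5; at small run
  counts this filter removes most pairs, so interaction analyses should
  budget hundreds to thousands of runs.
- The ORA sweep's raw p-values are not corrected across the grid.
- Multi-class phenotypes, probe-level normalization (RMA etc.) and
  non-Gaussian simulation are out of scope.
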