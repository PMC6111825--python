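# Methods

`subpathsig` identifies *subpathways* — connected gene sets inside pathway
gene–gene graphs — whose combined expression discriminates good- from
poor-prognosis patients, and condenses them into a Cox-weighted risk-score
signature that can be frozen and applied to external cohorts. This note
documents the model, the defaults and why they are what they are, the
numerical choices, and the limits of what the synthetic validation shows.

## Data model and normalization

Inputs are (a) per-pathway undirected, unweighted gene–gene graphs, (b) a
genes × samples expression matrix on raw-intensity or log2 scale, and (c) a
clinical table with overall-survival time (months), an event indicator, and
a binary good/poor prognosis label (poor = death observed). Expression is
log2-transformed if raw, then each gene is z-scored across samples using the
sample standard deviation (n−1); z-scoring makes genes commensurable so
their values can be averaged. Zero-variance genes have no defined z-score
and are dropped with a logged report rather than imputed. Every cohort —
training, test, or external — is z-scored *within itself*: cross-platform
cohorts share no absolute intensity scale, so a cohort's own z-scores are
the only transferable representation a frozen signature can consume.

## Subpathway activity and the greedy search

The activity of subpathway *k* in sample *j* is the combined z-score of its
member genes,

    a_kj = ( Σ_{i∈k} z_ij ) / n_k ,

a per-patient quantity. The divisor is configurable (`n` or `sqrt_n`; the
√n variant weighs large subpathways less conservatively) with plain `n` the
default. The discriminative score S of a subpathway is the Welch two-sample
t statistic of its activity vector between poor and good patients (signed
poor − good; the search ranks on |S| so that both over- and under-active
subpathways can be found — signatures legitimately contain members with
hazard ratios on either side of 1).

Every expression-mapped gene of a pathway seeds a greedy candidate. At each
step the neighbor gene of the current set whose addition maximizes |S| is
considered and accepted only if the new score exceeds (1 + r) × current
with improvement rate r = 0.05; requiring a 5% multiplicative gain is the
overfitting guard that stops the search. Grown sets with fewer than 4 or
more than 49 genes are discarded (too narrow or too broad to be a useful
functional unit), and identical gene sets reached from different seeds are
de-duplicated keeping the first seed in lexicographic order. Two ties are
broken deterministically: equal-gain neighbors resolve to the
lexicographically smallest symbol, and emitted lists depend only on the
input, never on iteration order of hash containers. Genes present in a
graph but absent from the expression matrix are invisible to the search —
they cannot score and are not usable as topological bridges.

## Permutation significance

Three complementary nulls are tested per candidate, each with p = M/N where
M counts permutations whose |S| strictly exceeds the real |S| (an optional
pseudocount mode computes (M+1)/(N+1) for users who need strictly positive
p-values):

1. **Gene-label permutation** (default 10 000 permutations): the assignment
   of expression rows to graph nodes is shuffled globally across the union
   of all pathways' expression-mapped genes, keeping expression and labels
   intact — does the subpathway depend on where its genes sit in the graph?
   A per-pathway shuffle is available as an option.
2. **Class-label permutation** (1000): the prognosis vector is shuffled —
   is the score tied to the actual prognosis status?
3. **Within-pathway permutation** (1000): random connected sets of the same
   size, anchored at the same seed gene, are grown by uniform random
   frontier expansion and scored — does the subpathway stand out inside its
   own pathway? Connectivity and seed anchoring are the two constraints the
   sampler preserves; when fewer genes than the subpathway's size are
   reachable from the seed the p-value is undefined and the record is
   flagged and excluded downstream.

Each test's p-values are Benjamini–Hochberg adjusted jointly across all
candidates, and a candidate survives only when all three FDRs fall strictly
below their thresholds — 1e-4 for test 1 and 1e-3 for tests 2 and 3, the
tighter first threshold reflecting its ten-fold larger permutation count.

A calibration caveat that matters for interpreting the tests: permutation
p-values of *greedy-search outputs* are anti-conservative by construction,
because the search maximized the very score being tested. The package's
null-calibration checks therefore draw random connected subpathways
(independent of the data, one per pathway so their gene sets are disjoint —
overlapping sets have correlated scores, which would invalidate a
uniformity test over the collection) and verify that all three p-values are
uniform under a no-effect cohort and that the triple-FDR filter passes
essentially nothing. The filter's practical role on search outputs is a strong relative
ranking, as in the original design.

## Random-forest narrowing

The significant subpathways' activity matrix feeds an iterative
random-forest elimination: at each iteration a bootstrap forest of
sqrt-mtry decision trees (default 10 000 trees) is fit to classify
good/poor; feature importance is the mean per-tree drop in out-of-bag
accuracy when that feature's column is permuted among the tree's OOB
samples; the floor(m/3) least important features (minimum 1) are discarded;
the OOB error is recorded; and the loop continues to two features. The
forest is built as bagged `max_features="sqrt"` trees (the classical
random-forest estimator) via an implementation that exposes per-tree
bootstrap membership, which the OOB importance needs.

The original selection of the retained set was a visual read of the OOB
error curve, which has no programmatic equivalent; the default stop rule is
the deterministic surrogate **min_plus_se**: the smallest retained set
whose OOB error is within one binomial standard error of the trace minimum.
The full trace (sizes, errors, importances) is exported so a user can pick
by eye instead. Under perfectly separable data the error trace is ~0
everywhere and this rule legitimately selects very small sets; the
elimination order, not the stop point, is then the informative output.

## Signature construction and application

Each selected subpathway gets a coefficient β_k from a univariate Cox
proportional-hazards fit of overall survival on its activity (partial
likelihood, Wald CI and p). For each of the 2^k − 1 non-empty subsets the
per-patient risk score Σ β_k a_kj is computed, patients are split at the
subset's median score (high iff *strictly* above), and subsets are ranked
by two-group log-rank p; the report records the best subset of every size
and the global winner (ties: smaller subset, then lexicographic member
order — parsimony and determinism). The winner is frozen as the signature:
member gene sets, β's, and the training-median cutoff.

Application to a new cohort recomputes activities from that cohort's own
z-scores and reuses β's and the cutoff verbatim — nothing is refit. Member
genes missing from the new platform are skipped with a warning and the
activity averages over the present genes (the only way to keep the combined
z-score well defined); a member with no mapped genes is an error. The
package also ships the published four-subpathway breast-cancer signature
(35 genes, coefficients 1.013 / 0.750 / 0.866 / −0.927, cutoff 0.1067) as
reference data for scoring breast-cancer cohorts directly.

## Evaluation statistics

* **Log-rank**: standard two-group statistic, hypergeometric variance at
  tied event times, 1-df chi-square p.
* **Kaplan–Meier**: product-limit curves; median survival is the earliest
  time with S(t) ≤ 0.5, undefined (None) when the curve never reaches 0.5.
* **Multivariate Cox with backward elimination**: complete cases only
  (subjects with missing covariates are dropped with a logged count; no
  imputation); starting from all covariates, the largest Wald p above the
  0.05 stay threshold is dropped and the model refit until all retained
  p ≤ 0.05. Convergence failures are retried once with a small ridge
  penalty before the offending term is dropped with a warning.
* **Time-dependent ROC**: cumulative-case / dynamic-control AUC at a fixed
  horizon with inverse-probability-of-censoring weights (Uno-type; case
  weight 1/G(T−) from the left-continuous censoring Kaplan–Meier, control
  weights constant and cancelling). With no censoring before the horizon
  this reduces exactly to the Mann–Whitney statistic, which the tests
  verify, alongside agreement with an independent IPCW implementation. The
  default horizon is the median of observed follow-up times regardless of
  event status (configurable). Two AUCs on the same samples are compared by
  a seeded paired bootstrap of the AUC difference with a two-sided normal
  test — a pragmatic choice where no canonical test is prescribed.
* **Stratified analysis**: a covariate predicate (e.g. ER status) subsets
  the cohort before log-rank/KM; pure plumbing.
* **Activity correlations**: pairwise Pearson between member activities
  (redundancy check); zero-variance rows yield flagged NaN entries.

## Synthetic cohorts

The generator emulates the pipeline's data model: each pathway graph is a
uniform-attachment random spanning tree plus extra random edges (connected
by construction; default 5 pathways × 30 genes, 30% extra edges);
expression is standard normal per gene on log2-like scale; a planted module
is a randomly grown connected gene set (default 5 genes) whose genes are
mean-shifted by δ (default 3 per-gene sd) in the poor class; survival is
exponential with log-hazard β_true × planted-module activity (default
β_true = 1, baseline median 80 months) under independent uniform censoring
targeting ~30% censored; the default cohort is 50 samples per class.
Effects are mean shifts on the z scale because that is the representation
the method consumes. A `structure_seed` lets an external-validation cohort
share graphs and module placement while drawing fresh patients.

What the generator does **not** emulate: microarray noise structure,
platform/batch effects, probe-to-gene mapping, gene–gene correlation beyond
the planted module, non-proportional hazards, and informative censoring.
Passing tests therefore demonstrate correctness and calibration of the
machinery under the stated generative model, not performance on real
cohorts.

## Problem sizes used in validation

The shipped checks run at desk scale, chosen to keep the statistical claims
testable: search-oracle verification brute-forces all neighbor additions on
20 random graphs of ≤10 nodes; null calibration uses 200 random connected
subpathways × 500 permutations per test; planted recovery uses 5 cohorts of
100 patients; Cox recovery uses n = 500; signature exhaustiveness
brute-forces all 63 subsets of 6 candidates; the end-to-end pipeline run
uses 1000/500/500 permutations and 300-tree forests. Defaults in the
library remain the full-scale values (10 000 permutations for test 1,
10 000 trees).

## Known limitations

* Greedy search is a local optimizer; it is verified locally maximal, not
  globally optimal (the small-graph oracle shows both when they coincide).
* p = M/N permits zero p-values; use the pseudocount option when
  downstream tooling requires p > 0.
* The median-split cutoff is cohort-internal and not clinically calibrated.
* The exact integer schedule of "discard one third" admits several
  readings; floor(m/3) with a minimum drop of 1 is used and exported in the
  trace.
* KGML ingestion is a minimal dialect (gene entries and relations only);
  group/compound/map semantics and relation subtypes are out of scope, as
  is any identifier aliasing: gene identity is the bare case-sensitive
  symbol.
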