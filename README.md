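# subpathsig

Prognosis-discriminative **subpathway activity signatures** from pathway
graphs and gene expression.

Gene-level prognostic signatures ignore the interaction structure of
biological pathways, while whole-pathway scores are too coarse. This
package works at the intermediate scale: it finds *subpathways* — connected
gene sets inside pathway gene–gene networks — whose per-patient combined
expression separates good- from poor-prognosis patients, and condenses them
into a compact, transferable risk-score signature for overall survival.
It is aimed at computational biologists building or validating survival
signatures on bulk expression cohorts (breast cancer being the motivating
application).

## Method

With per-gene z-scores `z_ij` (log2 expression, centered and scaled per
gene across samples), the activity of subpathway *k* in sample *j* is the
combined z-score of its `n_k` member genes

```
a_kj = ( Σ_{i∈k} z_ij ) / n_k
```

and its discriminative score `S_k` is the Welch *t* statistic of `a_k`
between poor and good prognosis classes. The pipeline:

1. **Greedy search** — from every seed gene, repeatedly add the neighbor
   gene maximizing `|S|`, accepting only if the new score exceeds
   `(1 + r)·S` with improvement rate `r = 0.05`; keep grown sets of 4–49
   genes.
2. **Triple permutation significance** — gene-label (10 000 permutations),
   class-label (1000) and within-pathway (1000) nulls, each `p = M/N`,
   Benjamini–Hochberg adjusted; keep subpathways with
   `FDR₁ < 1e-4`, `FDR₂ < 1e-3`, `FDR₃ < 1e-3` simultaneously.
3. **Random-forest narrowing** — iterative elimination (sqrt-mtry bootstrap
   forests, OOB permutation importance, discard the least important third
   per step) with the retained set read off the OOB error trace.
4. **Signature selection** — univariate Cox coefficients `β_k` per
   subpathway; over all `2^k − 1` member subsets, score patients with
   `risk_j = Σ β_k a_kj`, median-split (high iff strictly above), and keep
   the subset with the smallest log-rank p. The winner is frozen (genes,
   β's, cutoff) and applied verbatim to external cohorts on their own
   z-scores.
5. **Evaluation** — Kaplan–Meier / log-rank, uni- and multivariate Cox with
   backward elimination, IPCW time-dependent ROC, stratified (subtype)
   analysis, member-activity correlations.

A synthetic-cohort generator (connected random pathway graphs, planted
discriminative modules, exponential survival tied to module activity,
uniform censoring) makes every stage testable end to end; see
`docs/methods.md` for the model details and limitations.

## Worked example

```python
import numpy as np
from subpathsig import *
from subpathsig.activity_search import SearchConfig

cohort = simulate_cohort(SimulationConfig(seed=1))   # 100 patients, one planted 5-gene module
expr, clin = align_samples(cohort.expression, cohort.clinical)
z = normalize(expr)

subs = []
for g in cohort.graphs:
    subs.extend(greedy_search(g, z, clin.labels, SearchConfig(min_size=3)))

records = evaluate_significance(cohort.graphs, z, clin.labels, subs,
                                n_perm=(1000, 500, 500), seed=2)
keep = filter_significant(records)

act = build_activity_matrix(z, subs)
trace = rf_iterative_elimination(ActivityMatrix(act.data.loc[keep]),
                                 clin.labels, n_trees=300, seed=3)

sub_by_id = {sp.subpathway_id: sp for sp in subs}
sig, report = select_best_signature(list(trace.selected_ids), sub_by_id,
                                    ActivityMatrix(act.data.loc[keep]), clin)

table = apply_signature(sig, z)
chi2, p = logrank(table, clin)
auc = td_roc(table.scores, clin, float(np.median(clin.time)))
```

Output:

```
candidate subpathways: 51
significant after triple-FDR filter: 10
random-forest selection: ['P00_9', 'P00_11']
signature members: ['P00_11'], cutoff: 0.0126
training log-rank chi2 = 69.5, p = 7.61e-17; AUC = 0.846
planted-module Jaccard: 0.83
```

Reading the numbers: 51 connected candidates were grown; 10 survive all
three permutation nulls; the forest narrows them to two, and the exhaustive
subset scan keeps a one-member signature whose median-split groups differ
sharply in overall survival (log-rank p ≈ 8e-17) with good discrimination
at the median follow-up (AUC 0.85). The winning subpathway overlaps the
planted ground-truth module at Jaccard 0.83.

The same pipeline runs from the shell on plain TSV/JSON artifacts:

```sh
subpathsig all --config run.yaml --seed 7 --out results/
```

with subcommands `simulate`, `normalize`, `search`, `test`, `select`,
`signature`, `score`, `evaluate` for stage-by-stage runs. The published
four-subpathway breast-cancer signature (35 genes, frozen cutoff 0.1067) is
available as `subpathsig.published.published_signature()` for scoring a
breast-cancer cohort directly.

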