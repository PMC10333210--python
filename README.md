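# icisig

A pipeline for building and evaluating gene-expression classifiers of
pathological complete response (pCR) to immune-checkpoint inhibition
(ICI) plus chemotherapy in triple-negative breast cancer (TNBC).

## Scientific problem

Only a minority of TNBC patients reach pCR under neoadjuvant ICI plus
chemotherapy, and no routine biomarker separates likely responders from
non-responders before treatment. Given pre-treatment tumor expression
profiles with known outcomes, the goal is a classifier that (a) finds
genes whose expression differs between responders and non-responders,
(b) distills them into a compact signature, and (c) scores new patients
with a calibrated confidence that supports "reliable responder /
uncertain / reliable non-responder" decisions — while demonstrably not
manufacturing signal out of noise.

## Model

The pipeline chains five stages:

1. **Pan-cancer candidate screen.** Each cohort contributes a signed
   per-gene score `(−log10 p) · log2 n` (negative when the gene is down
   in responders), summed over cohorts; a missing gene contributes 0.
   The top 500 genes by absolute aggregate score become candidates.
2. **Differential expression.** Per gene, a pooled-variance Student
   t-test plus a Cheadle Z-ratio (z-transform per sample across genes,
   group mean difference divided by the SD of differences over genes).
   A gene is called DE when `p < 0.05` **and** `|Z-ratio| > 1.5`, both
   strict, with no multiple-testing correction (the downstream
   selection is what controls false discovery).
3. **Iterated random-forest backward elimination.** From the candidate
   set, repeatedly drop the least important 20% of genes (keeping
   `ceil(0.8·m)`) down to 2, choosing the set with the best
   out-of-bag-vote AUC (ties → smaller set). This runs B times with
   independent seeds; a frequency table counts how often each gene
   survives. Nested top-k signatures from that table are evaluated on a
   held-out split and the best k is chosen.
4. **Signature forest.** A random forest over the chosen genes; the
   confidence score of a sample is the fraction of trees voting
   "responder" (out-of-bag votes for training samples). Scores map to
   tiers: ≤ 0.4 reliable non-responder, ≥ 0.65 reliable responder,
   otherwise uncertain.
5. **Evaluation.** ROC AUC with DeLong 95% CI and p-value versus 0.5,
   Fisher exact tests and Haldane-corrected odds ratios on tier
   contingency tables, and cross-cohort application of a frozen model.

A seeded synthetic-cohort generator (planted signal genes with known
effect sizes, optional batch structure) provides ground truth for every
claim the test suite makes. ComBat batch correction (empirical-Bayes
via scanpy, plus an exact closed-form mode) and per-gene z-scoring
handle preprocessing.

## Worked example

End to end on a simulated cohort (1,000 genes, 20 signal genes at
effect size 0.6, 120 samples, 40% responders):

```python
from icisig import (SimulationDesign, simulate_cohort, zscore_by_gene,
                    stratified_split, call_differential, iterate_selection,
                    evaluate_topk, train_signature, score_samples, roc_auc,
                    tier_report)
from icisig.screen import (aggregate_panel, de_result_from_cohort,
                           select_top_scored)

design = SimulationDesign(n_genes=1000, n_signal=20, n_samples=120,
                          effect_size=0.6, response_rate=0.4)
cohort, truth = simulate_cohort(design, seed=7)
cohort = zscore_by_gene(cohort)
split = stratified_split(cohort, train_fraction=0.6, seed=7)

de = call_differential(split.train)
print(f"differentially expressed genes: {int(de['is_de'].sum())}")

candidates = select_top_scored(
    aggregate_panel([de_result_from_cohort(split.train)]), k=200)
freq = iterate_selection(split.train, candidates, B=50, master_seed=7,
                         n_trees=50)
curve = evaluate_topk(freq, split.train, split.validation,
                      k_grid=[5, 10, 15, 20, 30], n_trees=200, seed=7)
print(f"chosen signature size: {curve.chosen_k}")
print(f"validation AUC of chosen signature: {curve.chosen_auc:.3f}")

model = train_signature(split.train, list(curve.chosen_genes), seed=7,
                        n_trees=200)
scores = score_samples(model, split.validation)["score"]
r = roc_auc(scores, split.validation.y)
print(f"DeLong 95% CI: [{r.ci_low:.3f}, {r.ci_high:.3f}], p = {r.p_value:.2g}")
report = tier_report(scores, split.validation.y)
for tier, d in report.tiers.items():
    acc = "n/a" if d["accuracy"] is None else f"{d['accuracy']:.2f}"
    print(f"  {tier}: n = {d['n']}, accuracy = {acc}")
```

Output:

```text
differentially expressed genes: 64
chosen signature size: 20
validation AUC of chosen signature: 0.848
DeLong 95% CI: [0.724, 0.973], p = 4.6e-08
  reliable_non_responder: n = 24, accuracy = 0.92
  uncertain: n = 21, accuracy = n/a
  reliable_responder: n = 3, accuracy = 0.67
```

Of the 20 signature genes, 9 are planted signal genes; the reliable
tiers are far more accurate than the base rate while the uncertain tier
absorbs the ambiguous middle.

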