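# Methods note

This note records the statistical model, the parameter choices the
package fixes on its own authority, the scope of the synthetic-data
generator, numerical conventions, and known limitations. Every
empirical statement here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what those runs
measure.

## Statistical model

**Differential expression.** For gene *g* with responder values *a*
and non-responder values *b*, the package uses the pooled-variance
Student t-test (two-sided, `t` distribution with `n_a + n_b − 2`
degrees of freedom). The Z-ratio follows Cheadle's construction: each
sample's expression vector is z-transformed across genes, the per-gene
group difference of mean z is formed, and that difference is divided
by its SD over genes (n−1 denominator). A gene is called
differentially expressed when `p < 0.05` **and** `|Z-ratio| > 1.5`,
both strict inequalities, with no multiple-testing correction. Under a
standard normal, `P(|Z| > 1.5) = 0.1336`, which the null-calibration
test checks to ±0.02 on a 10,000-gene no-signal cohort; per-gene
p-values on the same cohort must pass a Kolmogorov–Smirnov uniformity
test at p > 0.01. Degenerate genes (zero pooled variance) report
`t = 0, p = 1`.

**Pan-cancer screen.** Each cohort contributes a signed score
`s = (−log10 p) · log2 n` per gene, negative when the gene is lower in
responders (direction taken from the t sign); the aggregate score is
the sum over cohorts, with unmeasured (gene, cohort) pairs
contributing 0. Candidates are the top 500 genes by absolute aggregate
score, ties broken lexicographically by symbol. `p = 0` underflow is
clamped to the smallest positive double with a warning.

**Feature selection.** Backward elimination starts from the candidate
set; each step keeps the `ceil(0.8·m)` most important genes (always
dropping at least one) down to a floor of 2. Importance is computed
once on the initial forest and carried along unless recomputation is
requested. The retained set within one run is the one with the highest
out-of-bag-vote AUC, ties resolved toward the smaller set. The run
repeats B times with independent seeds derived from a master seed via
`numpy.random.SeedSequence`; a frequency table counts how often each
gene appears in a run's selected set (mean elimination stage breaks
count ties, then symbol order). Nested top-k prefixes of the
frequency-ordered gene list are refit on the training split and scored
on the held-out split; the chosen k maximizes held-out AUC (ties →
smaller k).

**Classifier and tiers.** The signature model is a scikit-learn random
forest (fully grown trees, `sqrt` feature subsampling, bootstrap) over
the z-normalized signature genes. The confidence score is the fraction
of trees voting responder; for training samples, only out-of-bag trees
vote. Tiers are score ≤ 0.4 (reliable non-responder), ≥ 0.65 (reliable
responder), and strictly between (uncertain) — both cutoffs inclusive.
Cross-cohort application re-projects external samples using the
training cohort's per-gene mean/SD.

**Evaluation.** AUC uses midrank statistics; its variance, 95% CI
(Wald on the AUC scale, clipped to [0, 1]) and two-sided p-value
versus 0.5 follow DeLong. Odds ratios on 2×2 tables use the
cross-product with a Haldane–Anscombe +0.5 on *all* cells whenever any
cell is zero (applied to the OR and its log-scale Wald CI only);
Fisher's exact p is always computed on the raw counts via scipy. Batch
correction offers empirical-Bayes ComBat (scanpy's implementation of
the cited method) and a closed-form non-EB mode (standardize, remove
per-batch gene-wise mean/SD, restore) used for exactness tests.

## Package-fixed parameters

The following are the package's own scale choices, not pinned by the
underlying method: elimination forests use 50 trees and top-k
evaluation forests 200 trees in the reference scenarios (chosen once
from a runtime benchmark so that B = 100 iterations over 500
candidates fits a single-CPU minutes budget; production-scale defaults
remain 500 trees and B = 1000). Default importance is impurity-based;
out-of-bag permutation importance is implemented and switchable but
roughly an order of magnitude slower at screen scale. Train/validation
splits are stratified 60/40.

## Synthetic-data generator

`simulate_cohort` draws gene baselines `μ_g ~ N(7, 1.5)` and scales
`σ_g = |N(0.6, 0.2)| + 0.2`, assigns exactly `round(n · rate)`
responders (clipped to [2, n − 2], randomly permuted), optionally adds
per-batch gene offsets and noise multipliers with batch membership
stratified by response, and shifts each planted signal gene by
`δ_g · σ_g` in responders. The generator covers continuous
(log-intensity-like) expression with independent genes; it does not
model gene–gene correlation, count noise, or missing values. All
randomness flows from integer seeds through `SeedSequence`; panel
cohorts derive child seeds from the master seed and cohort index, kept
below 2³¹.

## Reference scenarios

`icisig.benchmarks` holds the study-condition scenarios shared by the
acceptance tests and `scripts/acceptance.py`: null calibration (10,000
genes, n = 100); screen recovery on a 9-cohort panel (cohort sizes
30–350, 600 shared signal genes at δ = 1, recovery ≥ 70% of the
top 500 and < 15% after label permutation); end-to-end pipeline
recovery (2,000 genes, 30 planted at δ = 1, n = 150, B = 100,
validation AUC ≥ 0.80 and Mann–Whitney p < 0.01 for planted-vs-noise
selection frequencies); overfitting control (DE-signature forests on
null cohorts stay in AUC [0.3, 0.7] for ≥ 90% of 20 seeds);
specificity control (a signal-trained model on an independent null
cohort — the chemotherapy-only analog — stays in [0.3, 0.7] for ≥ 90%
of 10 seeds); and hybrid redundancy (signature-mean features built
from genes the model already sees raise mean validation AUC by
< 0.05 over 10 seeds at δ = 1).

## Limitations

- No multiple-testing correction at the DE stage is intentional
  (selection happens downstream), so DE counts on null data run near
  the nominal joint rate (~4–5% of genes), not zero.
- The hybrid-redundancy result is regime-dependent: at δ = 1 the
  forests operate near the AUC ceiling and the hybrid gain is ≈ 0. Off
  the ceiling (δ ≈ 0.4) a signature mean — a denoised linear
  combination an axis-aligned forest cannot construct from its inputs
  — can genuinely add ~0.05 AUC. "Redundant features add nothing"
  should be read as a statement about strong-signal regimes.
- DeLong CIs are Wald-type on the AUC scale and degenerate at
  AUC = 1; the p-value is clamped to ≥ 1e-300.
- Model bundles store the z-normalized training matrix and refit the
  forest deterministically on load rather than serializing trees;
  loading therefore costs one forest fit.
- The generator's independence assumption means recovery fractions on
  simulated data are optimistic relative to correlated real
  transcriptomes; the scenarios validate the machinery, not clinical
  performance.
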