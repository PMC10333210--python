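"""Standard simulation scenarios exercising the pipeline end to end.

Each function sets up one of the package's reference study conditions —
null calibration, pan-cancer screen recovery, full pipeline recovery,
overfitting/specificity controls, and hybrid redundancy — runs the
relevant pipeline stages, and returns the measured quantities.  They
are used both by the test suite and by the results-reproduction script.

Problem sizes are chosen to emulate the target study's structure
(cohorts of tens to a few hundred patients, a minority of signal genes,
effects around one per-gene SD) at a scale a single CPU handles in
minutes; the methods note documents each choice.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .diffexp import call_differential, t_test_by_gene, z_ratio
from .evaluate import GeneSetCollection, build_hybrid, roc_auc, score_hybrid
from .featsel import evaluate_topk, iterate_selection
from .io import ExpressionCohort
from .model import apply_cross_cohort, score_samples, train_signature
from .preprocess import stratified_split, zscore_by_gene
from .screen import aggregate_panel, de_result_from_cohort, select_top_scored
from .simulate import (SimulatedTruth, SimulationDesign, gene_universe,
                       simulate_cohort, simulate_null_cohort,
                       simulate_screen_panel)


def null_calibration(seed: int = 1, n_genes: int = 10_000, n_samples: int = 100) -> dict:
    """Per-gene test calibration on a cohort with no planted signal.

    Returns the KS uniformity p-value of the t-test p-values and the
    fraction of genes with |Z-ratio| > 1.5 (standard-normal expectation
    0.1336).
    """
    design = SimulationDesign(n_genes=n_genes, n_signal=0, n_samples=n_samples)
    cohort = simulate_null_cohort(design, seed)
    p = t_test_by_gene(cohort)["p"]
    zr = z_ratio(cohort)
    de = call_differential(cohort)
    return {
        "ks_uniformity_p": float(stats.kstest(p, "uniform").pvalue),
        "zratio_tail_fraction": float((zr.abs() > 1.5).mean()),
        "de_fraction": float(de["is_de"].mean()),
        "n_genes": n_genes,
        "n_samples": n_samples,
    }


def screen_recovery(
    seed: int = 1,
    n_genes: int = 10_000,
    n_shared_signal: int = 600,
    effect_size: float = 1.0,
    cohort_sizes: tuple[int, ...] = (30, 50, 80, 120, 160, 200, 250, 300, 350),
    top_k: int = 500,
) -> dict:
    """Planted-gene recovery of the pan-cancer screen on a 9-cohort panel.

    Measures the fraction of the top-k aggregate-scored genes that are
    planted signal genes, before and after permuting the response
    labels in every cohort.
    """
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    idx = rng.choice(n_genes, n_shared_signal, replace=False)
    signs = rng.choice([-1.0, 1.0], n_shared_signal)
    truth = SimulatedTruth(
        signal_genes=[genes[i] for i in sorted(idx)],
        effects={genes[i]: float(s * effect_size) for i, s in zip(idx, signs)},
    )
    designs = [
        SimulationDesign(n_genes=n_genes, n_signal=0, n_samples=n,
                         cohort_id="panel")
        for n in cohort_sizes
    ]
    panel = simulate_screen_panel(designs, truth, seed)
    results = [de_result_from_cohort(c) for c, _ in panel]
    top = select_top_scored(aggregate_panel(results), top_k)
    signal = set(truth.signal_genes)
    recovered = len(set(top) & signal) / top_k

    perm_results = []
    for c, _ in panel:
        cp = c.copy()
        cp.response = rng.permutation(cp.response)
        perm_results.append(de_result_from_cohort(cp))
    perm_top = select_top_scored(aggregate_panel(perm_results), top_k)
    permuted = len(set(perm_top) & signal) / top_k
    return {
        "recovery_fraction": float(recovered),
        "permuted_recovery_fraction": float(permuted),
        "n_cohorts": len(designs),
        "top_k": top_k,
    }


def pipeline_recovery(
    seed: int = 1,
    n_genes: int = 2000,
    n_signal: int = 30,
    n_samples: int = 150,
    effect_size: float = 1.0,
    n_candidates: int = 500,
    B: int = 100,
    n_trees: int = 50,
    eval_trees: int = 200,
    k_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 37, 45, 60),
) -> dict:
    """End-to-end parameter recovery on a TNBC-like simulated cohort.

    Screens candidates on the training split, runs B elimination
    iterations, evaluates the nested top-k signatures on the held-out
    validation split, and compares frequency-table counts of planted
    versus noise genes (one-sided Mann-Whitney).
    """
    design = SimulationDesign(n_genes=n_genes, n_signal=n_signal,
                             n_samples=n_samples, effect_size=effect_size)
    cohort, truth = simulate_cohort(design, seed)
    cohort = zscore_by_gene(cohort)
    split = stratified_split(cohort, 0.6, seed)
    candidates = select_top_scored(
        aggregate_panel([de_result_from_cohort(split.train)]), n_candidates
    )
    freq = iterate_selection(split.train, candidates, B=B, master_seed=seed,
                             n_trees=n_trees)
    planted_mask = freq.counts.index.isin(truth.signal_genes)
    planted = freq.counts[planted_mask]
    noise = freq.counts[~planted_mask]
    _, mw_p = stats.mannwhitneyu(planted, noise, alternative="greater")
    curve = evaluate_topk(freq, split.train, split.validation, list(k_grid),
                          n_trees=eval_trees, seed=seed)
    return {
        "validation_auc": float(curve.chosen_auc),
        "chosen_k": int(curve.chosen_k),
        "mannwhitney_p": float(mw_p),
        "median_count_planted": float(planted.median()),
        "median_count_noise": float(noise.median()),
        "k_curve": {int(k): float(a) for k, (_, a) in curve.entries.items()},
        "B": B,
        "n_candidates": len(candidates),
    }


def _de_signature_features(train: ExpressionCohort, fallback: int = 10) -> list[str]:
    """DE genes of a cohort at the standard thresholds (top-p fallback)."""
    table = call_differential(train)
    genes = list(table.index[table["is_de"]])
    if len(genes) < 2:
        genes = list(table["p"].nsmallest(fallback).index)
    return genes


def de_signature_null_control(
    seed: int = 1,
    n_seeds: int = 20,
    n_genes: int = 5000,
    n_samples: int = 100,
    n_trees: int = 200,
) -> dict:
    """Overfitting control: raw DE-signature forests on null cohorts.

    For each replicate a cohort with label-independent expression is
    split 60/40, the training split's DE genes become the features, and
    the validation AUC is recorded.  An honest pipeline shows chance
    performance; the fraction of replicates with AUC in [0.3, 0.7] is
    returned.
    """
    design = SimulationDesign(n_genes=n_genes, n_signal=0, n_samples=n_samples)
    aucs = []
    for r in range(n_seeds):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31)
        cohort = zscore_by_gene(simulate_null_cohort(design, rep_seed))
        split = stratified_split(cohort, 0.6, rep_seed)
        features = _de_signature_features(split.train)
        model = train_signature(split.train, features, seed=rep_seed,
                                n_trees=n_trees)
        scores = score_samples(model, split.validation)["score"]
        aucs.append(roc_auc(scores, split.validation.y).auc)
    aucs = np.asarray(aucs)
    return {
        "aucs": [float(a) for a in aucs],
        "fraction_in_chance_band": float(((aucs >= 0.3) & (aucs <= 0.7)).mean()),
        "n_seeds": n_seeds,
    }


def cross_null_specificity(
    seed: int = 1,
    n_seeds: int = 10,
    n_genes: int = 2000,
    n_signal: int = 30,
    n_samples: int = 150,
    effect_size: float = 1.0,
    signature_size: int = 30,
    n_trees: int = 200,
) -> dict:
    """Specificity control: signal-trained model on independent null data.

    Mirrors applying an ICI-response signature to patients treated with
    chemotherapy alone, where it should be uninformative (AUC near
    0.5).
    """
    design = SimulationDesign(n_genes=n_genes, n_signal=n_signal,
                             n_samples=n_samples, effect_size=effect_size)
    aucs = []
    for r in range(n_seeds):
        rep_seed = int(np.random.SeedSequence([seed, 7, r]).generate_state(1)[0] % 2**31)
        cohort, truth = simulate_cohort(design, rep_seed)
        cohort = zscore_by_gene(cohort)
        genes = truth.signal_genes[:signature_size]
        model = train_signature(cohort, genes, seed=rep_seed, n_trees=n_trees)
        null = zscore_by_gene(simulate_null_cohort(design, rep_seed + 1))
        scores = apply_cross_cohort(model, null)
        aucs.append(roc_auc(scores, null.y).auc)
    aucs = np.asarray(aucs)
    return {
        "aucs": [float(a) for a in aucs],
        "fraction_in_chance_band": float(((aucs >= 0.3) & (aucs <= 0.7)).mean()),
        "n_seeds": n_seeds,
    }


def hybrid_redundancy(
    seed: int = 1,
    n_seeds: int = 10,
    n_genes: int = 600,
    n_signal: int = 30,
    n_samples: int = 150,
    effect_size: float = 1.0,
    n_trees: int = 200,
) -> dict:
    """Hybrid-versus-gene-only comparison with fully redundant signatures.

    Signature features are means of the planted genes (split by
    direction), i.e. deterministic functions of features the gene-only
    model already sees; merging them should not improve validation AUC.
    Returns per-seed AUCs and the mean difference (hybrid - gene-only).
    """
    design = SimulationDesign(n_genes=n_genes, n_signal=n_signal,
                             n_samples=n_samples, effect_size=effect_size)
    gene_aucs, hybrid_aucs = [], []
    for r in range(n_seeds):
        rep_seed = int(np.random.SeedSequence([seed, 11, r]).generate_state(1)[0] % 2**31)
        cohort, truth = simulate_cohort(design, rep_seed)
        cohort = zscore_by_gene(cohort)
        split = stratified_split(cohort, 0.6, rep_seed)
        genes = truth.signal_genes
        up = {g for g, e in truth.effects.items() if e > 0}
        down = set(genes) - up
        sets = {"UP_SET": up, "DOWN_SET": down, "ALL_SET": set(genes)}
        sets = GeneSetCollection({k: v for k, v in sets.items() if v})

        plain = train_signature(split.train, genes, seed=rep_seed, n_trees=n_trees)
        g_scores = score_samples(plain, split.validation)["score"]
        gene_aucs.append(roc_auc(g_scores, split.validation.y).auc)

        hybrid = build_hybrid(split.train, genes, sets, seed=rep_seed,
                              n_trees=n_trees)
        h_scores = score_hybrid(hybrid, split.validation)
        hybrid_aucs.append(roc_auc(h_scores, split.validation.y).auc)
    gene_aucs = np.asarray(gene_aucs)
    hybrid_aucs = np.asarray(hybrid_aucs)
    return {
        "gene_aucs": [float(a) for a in gene_aucs],
        "hybrid_aucs": [float(a) for a in hybrid_aucs],
        "mean_auc_difference": float((hybrid_aucs - gene_aucs).mean()),
        "n_seeds": n_seeds,
    }
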