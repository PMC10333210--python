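"""Backward-elimination, frequency-table and top-k curve tests.

Forests here are deliberately small (tens of trees) — the properties
under test are structural (set sizes, determinism, accounting
identities) or need only coarse signal recovery.
"""

import numpy as np
import pytest
from scipy import stats

from icisig import (SimulationDesign, evaluate_topk, iterate_selection,
                    rf_backward_eliminate, simulate_cohort, stratified_split,
                    zscore_by_gene)
from icisig.featsel import _fit_forest, elimination_set_sizes
from icisig.io import ValidationError


class TestEliminationTrace:
    def test_set_sizes_follow_ceil_rule(self):
        sizes = elimination_set_sizes(100, 0.2)
        assert sizes[:5] == [100, 80, 64, 52, 42]
        assert sizes[-1] == 2
        for a, b in zip(sizes, sizes[1:]):
            assert b == max(min(int(np.ceil(0.8 * a)), a - 1), 2)

    def test_two_candidates_floor(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:2]
        trace = rf_backward_eliminate(split.train, genes, n_trees=30, seed=1)
        assert len(trace.steps) == 1
        assert set(trace.selected_genes) == set(genes)

    def test_sizes_strictly_decreasing_and_selection_rule(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes + split.train.genes[:25]
        genes = list(dict.fromkeys(genes))
        trace = rf_backward_eliminate(split.train, genes, n_trees=40, seed=3)
        sizes = [len(gs) for gs, _ in trace.steps]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        best_auc = max(a for _, a in trace.steps)
        assert trace.selected_auc == best_auc
        # ties go to the smaller set
        tied = [len(gs) for gs, a in trace.steps if a == best_auc]
        assert len(trace.selected_genes) == min(tied)

    def test_recovers_planted_genes(self):
        # 5 strong planted genes among 50 noise genes: the selected set
        # should contain most of them in most seeds
        design = SimulationDesign(n_genes=55, n_signal=5, n_samples=200,
                                  effect_size=2.0)
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cohort, truth = simulate_cohort(design, 100 + seed)
            cohort = zscore_by_gene(cohort)
            trace = rf_backward_eliminate(cohort, cohort.genes, n_trees=80,
                                          seed=seed)
            if len(set(trace.selected_genes) & set(truth.signal_genes)) >= 4:
                hits += 1
        assert hits >= int(0.75 * n_seeds)

    def test_oob_permutation_importance_mode(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:5] + split.train.genes[:10]
        genes = list(dict.fromkeys(genes))
        trace = rf_backward_eliminate(split.train, genes, n_trees=60, seed=2,
                                      importance="oob_permutation")
        assert len(set(trace.selected_genes) & set(truth.signal_genes[:5])) >= 3

    def test_single_class_rejected(self, signal_split):
        split, truth = signal_split
        only_resp = split.train.subset_samples(
            np.flatnonzero(split.train.response == "responder").tolist()
        )
        with pytest.raises(ValidationError):
            rf_backward_eliminate(only_resp, truth.signal_genes[:4], seed=0)


class TestIterateSelection:
    def test_b1_counts_are_indicator(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:3] + split.train.genes[:7]
        genes = list(dict.fromkeys(genes))
        freq = iterate_selection(split.train, genes, B=1, master_seed=5, n_trees=30)
        assert set(freq.counts.unique()) <= {0, 1}
        assert freq.B == 1

    def test_accounting_identity_and_determinism(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:4] + split.train.genes[:8]
        genes = list(dict.fromkeys(genes))
        freq1 = iterate_selection(split.train, genes, B=5, master_seed=9, n_trees=30)
        freq2 = iterate_selection(split.train, genes, B=5, master_seed=9, n_trees=30)
        assert (freq1.counts == freq2.counts).all()
        assert (freq1.mean_stage == freq2.mean_stage).all()
        assert (freq1.counts <= 5).all()

    def test_planted_genes_rank_above_noise(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:8] + split.train.genes[:40]
        genes = list(dict.fromkeys(genes))
        freq = iterate_selection(split.train, genes, B=15, master_seed=1, n_trees=40)
        planted = freq.counts[freq.counts.index.isin(truth.signal_genes)]
        noise = freq.counts[~freq.counts.index.isin(truth.signal_genes)]
        u, p = stats.mannwhitneyu(planted, noise, alternative="greater")
        assert p < 0.01

    def test_bootstrap_mode_runs(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:3] + split.train.genes[:5]
        genes = list(dict.fromkeys(genes))
        freq = iterate_selection(split.train, genes, B=2, master_seed=0,
                                 n_trees=30, bootstrap=True)
        assert freq.B == 2


class TestEvaluateTopk:
    def test_nestedness(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:6] + split.train.genes[:20]
        genes = list(dict.fromkeys(genes))
        freq = iterate_selection(split.train, genes, B=4, master_seed=2, n_trees=30)
        curve = evaluate_topk(freq, split.train, split.validation,
                              [5, 10, 20], n_trees=40, seed=2)
        assert set(curve.entries[5][0]) < set(curve.entries[10][0])
        assert set(curve.entries[10][0]) < set(curve.entries[20][0])
        assert all(0 <= a <= 1 for _, a in curve.entries.values())

    def test_saturation_equals_plain_forest(self, signal_split):
        from sklearn.metrics import roc_auc_score

        split, truth = signal_split
        genes = truth.signal_genes[:4] + split.train.genes[:8]
        genes = list(dict.fromkeys(genes))
        freq = iterate_selection(split.train, genes, B=3, master_seed=4, n_trees=30)
        k = len(genes)
        curve = evaluate_topk(freq, split.train, split.validation, [k],
                              n_trees=50, seed=11)
        ordered = freq.ordered_genes()
        clf = _fit_forest(split.train.X[:, split.train.gene_index(ordered)],
                          split.train.y, 50, 11)
        col = int(np.flatnonzero(clf.classes_ == 1)[0])
        scores = clf.predict_proba(
            split.validation.X[:, split.validation.gene_index(ordered)]
        )[:, col]
        expected = roc_auc_score(split.validation.y, scores)
        assert curve.entries[k][1] == pytest.approx(expected, abs=1e-12)

    def test_fixed_k_mode(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:5] + split.train.genes[:10]
        genes = list(dict.fromkeys(genes))
        freq = iterate_selection(split.train, genes, B=2, master_seed=3, n_trees=30)
        curve = evaluate_topk(freq, split.train, split.validation,
                              [3, 6, 9], n_trees=30, seed=0, fixed_k=6)
        assert curve.chosen_k == 6

    def test_leakage_guard(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:3]
        freq = iterate_selection(split.train, genes, B=1, master_seed=0, n_trees=30)
        with pytest.raises(ValidationError, match="shares samples"):
            evaluate_topk(freq, split.train, split.train, [2], n_trees=30, seed=0)
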