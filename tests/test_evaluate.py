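"""ROC/AUC, odds-ratio, tier-report, signature-score and hybrid tests."""

import numpy as np
import pytest
from scipy import stats

from icisig import (GeneSetCollection, build_hybrid, odds_ratio, roc_auc,
                    score_hybrid, signature_score, tier_report,
                    train_signature, score_samples)
from icisig.evaluate import tier_contingency
from icisig.io import ValidationError
from icisig.model import (RELIABLE_NON_RESPONDER, RELIABLE_RESPONDER,
                          UNCERTAIN)


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney count with 0.5 credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_worked_example(self):
        # pairs: (0.35,0.1)+, (0.35,0.4)-, (0.8,0.1)+, (0.8,0.4)+ -> 3/4
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        r = roc_auc([0.5] * 8, [1, 0] * 4)
        assert r.auc == 0.5

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            # coarse grid forces ties
            scores = rng.choice(np.linspace(0, 1, 7), n)
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert r.ci_low <= r.auc <= r.ci_high
            assert 0 < r.p_value <= 1

    def test_antisymmetry(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.uniform(size=30) > 0.5).astype(int)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc \
            == pytest.approx(1.0, abs=1e-12)

    def test_delong_p_calibration(self, rng):
        # informative scores: small p; pure-noise scores: typically large
        labels = np.array([1] * 30 + [0] * 30)
        strong = np.concatenate([rng.normal(2, 1, 30), rng.normal(0, 1, 30)])
        noise = rng.normal(size=60)
        assert roc_auc(strong, labels).p_value < 0.001
        assert roc_auc(noise, labels).p_value > 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestOddsRatio:
    def test_printed_tier_counts(self):
        # 19/20 reliable responders with pCR vs 1/9 reliable
        # non-responders: cross-product OR = 19*8 / (1*1)
        r = odds_ratio([[19, 1], [1, 8]])
        assert r.odds_ratio == pytest.approx(152.0)
        assert r.fisher_p < 0.001

    def test_no_association(self):
        r = odds_ratio([[1, 1], [1, 1]])
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.fisher_p == pytest.approx(1.0)

    def test_haldane_correction(self):
        r = odds_ratio([[5, 0], [0, 5]])
        assert r.odds_ratio == pytest.approx(121.0)  # (5.5*5.5)/(0.5*0.5)
        assert np.isfinite(r.ci_low) and np.isfinite(r.ci_high)

    def test_fisher_invariant_to_transpose(self, rng):
        t = rng.integers(1, 20, size=(2, 2))
        assert odds_ratio(t).fisher_p == pytest.approx(odds_ratio(t.T).fisher_p)

    def test_reciprocal_property(self):
        a, b, c, d = 7, 3, 2, 9
        r1 = odds_ratio([[a, b], [c, d]])
        r2 = odds_ratio([[b, a], [d, c]])
        assert r1.odds_ratio * r2.odds_ratio == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            odds_ratio([[0, 0], [3, 4]])

    def test_ci_contains_or(self, rng):
        t = rng.integers(1, 30, size=(2, 2))
        r = odds_ratio(t)
        assert r.ci_low <= r.odds_ratio <= r.ci_high


class TestTierReport:
    def test_all_responders_high_scores(self):
        report = tier_report([1.0] * 6, [1] * 6)
        tier = report.tiers[RELIABLE_RESPONDER]
        assert tier["n"] == 6 and tier["accuracy"] == 1.0

    def test_partition(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, 40)
        report = tier_report(scores, labels)
        assert report.total == 40

    def test_hand_tallied_fixture(self):
        scores = np.array([0.1, 0.3, 0.4, 0.45, 0.5, 0.6, 0.64, 0.65,
                           0.7, 0.9, 1.0, 0.2])
        labels = np.array([0, 0, 1, 0, 1, 1, 0, 1, 1, 1, 1, 0])
        report = tier_report(scores, labels)
        low = report.tiers[RELIABLE_NON_RESPONDER]
        mid = report.tiers[UNCERTAIN]
        high = report.tiers[RELIABLE_RESPONDER]
        assert (low["n"], low["n_pcr"]) == (4, 1)      # 0.1,0.3,0.4,0.2
        assert (mid["n"], mid["n_pcr"]) == (4, 2)      # 0.45,0.5,0.6,0.64
        assert (high["n"], high["n_pcr"]) == (4, 4)    # 0.65,0.7,0.9,1.0
        assert low["accuracy"] == pytest.approx(3 / 4)
        assert high["accuracy"] == pytest.approx(1.0)
        assert mid["accuracy"] is None

    def test_tier_contingency_modes(self, rng):
        scores = rng.uniform(size=60)
        labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        for mode in ("high_vs_rest", "upper_tertile"):
            r = tier_contingency(scores, labels, mode=mode)
            assert r.table.sum() == 60


class TestSignatureScore:
    def test_singleton_equals_gene_zscore(self, small_cohort):
        s = signature_score(small_cohort, {"GENE3"})
        row = small_cohort.values[3]
        expected = (row - row.mean()) / row.std(ddof=1)
        np.testing.assert_allclose(s.to_numpy(), expected, atol=1e-12)

    def test_mean_oracle_on_three_genes(self, small_cohort):
        genes = ["GENE1", "GENE4", "GENE7"]
        s = signature_score(small_cohort, genes)
        zs = []
        for g in genes:
            row = small_cohort.values[small_cohort.genes.index(g)]
            zs.append((row - row.mean()) / row.std(ddof=1))
        np.testing.assert_allclose(s.to_numpy(), np.mean(zs, axis=0), atol=1e-12)

    def test_full_gene_set_centers_near_zero(self, small_cohort):
        s = signature_score(small_cohort, small_cohort.genes)
        assert abs(s.mean()) < 1e-12

    def test_absent_genes_dropped_or_error(self, small_cohort):
        s = signature_score(small_cohort, {"GENE2", "ZZZNOT"})
        row = small_cohort.values[2]
        np.testing.assert_allclose(
            s.to_numpy(), (row - row.mean()) / row.std(ddof=1), atol=1e-12
        )
        with pytest.raises(ValidationError):
            signature_score(small_cohort, {"ZZZNOT"})


class TestHybrid:
    def test_empty_signature_collection_reduces_to_gene_model(self, signal_split):
        split, truth = signal_split
        genes = truth.signal_genes[:6]
        hybrid = build_hybrid(split.train, genes, GeneSetCollection(), seed=7,
                              n_trees=50)
        plain = train_signature(split.train, genes, seed=7, n_trees=50)
        hs = score_hybrid(hybrid, split.validation)
        ps = score_samples(plain, split.validation)["score"]
        np.testing.assert_array_equal(hs.to_numpy(), ps.to_numpy())

    def test_feature_count(self, signal_split):
        split, truth = signal_split
        sets = GeneSetCollection({
            "TCELL": set(truth.signal_genes[:3]),
            "BCELL": set(truth.signal_genes[3:6]),
        })
        hybrid = build_hybrid(split.train, truth.signal_genes[:4], sets, seed=1,
                              n_trees=30)
        assert len(hybrid.feature_names) == 4 + 2

    def test_signatures_only_mode(self, signal_split):
        # mean-z of concordantly upregulated signal genes is predictive;
        # a mixed up/down set would cancel
        split, truth = signal_split
        up = [g for g, e in truth.effects.items() if e > 0]
        sets = GeneSetCollection({"SIG": set(up)})
        hybrid = build_hybrid(split.train, [], sets, seed=1, n_trees=50)
        scores = score_hybrid(hybrid, split.validation)
        assert ((scores >= 0) & (scores <= 1)).all()
        auc = roc_auc(scores, split.validation.y).auc
        assert auc > 0.6  # a signal-gene mean is itself predictive

    def test_empty_feature_set_rejected(self, signal_split):
        split, _ = signal_split
        with pytest.raises(ValidationError):
            build_hybrid(split.train, [], GeneSetCollection(), seed=0)
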