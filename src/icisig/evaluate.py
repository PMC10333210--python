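"""Evaluation statistics: ROC/AUC, odds ratios, tier reports, signatures.

AUC is the Mann-Whitney statistic (0.5 credit for ties); its 95%
confidence interval and the two-sided p-value against AUC = 0.5 use the
DeLong covariance estimator.  Odds ratios are the 2x2 cross-product
with the Haldane-Anscombe +0.5 correction applied to every cell when
any cell is zero, a Wald log-scale confidence interval, and a two-sided
Fisher exact p-value computed on the raw counts.

Molecular signature scores (T-cell, B-cell, mitotic rate, PD-1/PD-L1
expression, ...) are the mean of per-gene z-scores over the set's genes
present in the cohort; a hybrid classifier merges such scores with
individual gene expression into one random-forest feature table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .featsel import _fit_forest, _oob_votes
from .io import ExpressionCohort, GeneSetCollection, ValidationError

logger = logging.getLogger("icisig")

_P_FLOOR = 1e-300


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int


@dataclass
class ContingencyResult:
    table: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float


@dataclass
class TierReport:
    """Per-tier patient counts and predictive accuracy.

    Accuracy is pCR fraction for the reliable-responder tier and
    residual-disease fraction for the reliable-non-responder tier; the
    uncertain tier reports its pCR fraction descriptively (``accuracy``
    is None there).
    """

    tiers: dict[str, dict] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(t["n"] for t in self.tiers.values())


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong inference
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels) -> RocResult:
    """AUC with DeLong 95% CI and two-sided p-value versus 0.5.

    ``labels`` are binary (1 = responder / pCR).  The point estimate is
    the Mann-Whitney U statistic scaled to [0, 1] with 0.5 credit for
    tied scores; the CI is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(labels) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 1 or n < 1:
        raise ValidationError("need at least one positive and one negative")

    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = tz[:m].sum() / (m * n) - (m + 1) / (2 * n)
    v01 = (tz[:m] - tx) / n          # structural components for positives
    v10 = 1.0 - (tz[m:] - ty) / m    # and negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    var = s01 / m + s10 / n
    se = float(np.sqrt(var))
    if se > 0:
        ci_low = max(0.0, auc - 1.959963984540054 * se)
        ci_high = min(1.0, auc + 1.959963984540054 * se)
        z = (auc - 0.5) / se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        ci_low = ci_high = auc
        p = 1.0 if auc == 0.5 else _P_FLOOR
    p = max(min(p, 1.0), _P_FLOOR)
    return RocResult(auc=float(auc), ci_low=float(ci_low), ci_high=float(ci_high),
                     p_value=p, n_pos=m, n_neg=n)


def auc_bootstrap_ci(scores, labels, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the AUC (stratified resampling)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pb = rng.choice(pos, len(pos))
        nb = rng.choice(neg, len(neg))
        aucs[b] = roc_auc(
            np.concatenate([pb, nb]),
            np.concatenate([np.ones(len(pb), int), np.zeros(len(nb), int)]),
        ).auc
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Odds ratio / Fisher exact test
# ---------------------------------------------------------------------------


def odds_ratio(table) -> ContingencyResult:
    """Cross-product odds ratio for a 2x2 exposure-by-outcome table.

    When any cell is zero, 0.5 is added to every cell for the OR and
    its Wald CI (Haldane-Anscombe); the Fisher exact p always uses the
    raw counts.  A zero margin (empty row or column) is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("counts must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("zero margin: association undefined")
    raw = t.astype(int)
    work = t + 0.5 if (t == 0).any() else t
    a, b = work[0]
    c, d = work[1]
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(oratio) - 1.959963984540054 * se))
    ci_high = float(np.exp(np.log(oratio) + 1.959963984540054 * se))
    _, fisher_p = stats.fisher_exact(raw, alternative="two-sided")
    return ContingencyResult(table=raw, odds_ratio=float(oratio),
                             ci_low=ci_low, ci_high=ci_high,
                             fisher_p=float(fisher_p))


def tier_contingency(scores, labels, tier_low: float = 0.4, tier_high: float = 0.65,
                     mode: str = "high_vs_rest") -> ContingencyResult:
    """2x2 association between tier membership and pCR.

    ``high_vs_rest`` contrasts the reliable-responder tier against all
    other samples; ``upper_tertile`` contrasts the top third of scores
    against the lower two thirds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if mode == "high_vs_rest":
        exposed = scores >= tier_high
    elif mode == "upper_tertile":
        exposed = scores >= np.quantile(scores, 2 / 3)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table = [
        [int(((exposed) & (labels == 1)).sum()), int(((exposed) & (labels == 0)).sum())],
        [int(((~exposed) & (labels == 1)).sum()), int(((~exposed) & (labels == 0)).sum())],
    ]
    return odds_ratio(table)


def tier_report(scores, labels, tier_low: float = 0.4, tier_high: float = 0.65) -> TierReport:
    """Count samples and pCR outcomes in each confidence-score tier."""
    from .model import (RELIABLE_NON_RESPONDER, RELIABLE_RESPONDER, UNCERTAIN,
                        categorize_with)

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    tiers = categorize_with(scores, tier_low, tier_high)
    report: dict[str, dict] = {}
    for name in (RELIABLE_NON_RESPONDER, UNCERTAIN, RELIABLE_RESPONDER):
        mask = tiers == name
        n = int(mask.sum())
        n_pcr = int(labels[mask].sum())
        if name == RELIABLE_RESPONDER:
            acc = n_pcr / n if n else None
        elif name == RELIABLE_NON_RESPONDER:
            acc = (n - n_pcr) / n if n else None
        else:
            acc = None
        report[name] = {
            "n": n,
            "n_pcr": n_pcr,
            "pcr_fraction": n_pcr / n if n else None,
            "accuracy": acc,
        }
    return TierReport(tiers=report)


# ---------------------------------------------------------------------------
# Molecular signature scores and hybrid classifiers
# ---------------------------------------------------------------------------


def signature_score(cohort: ExpressionCohort, gene_set) -> pd.Series:
    """Mean per-gene z-score over the set's genes present in the cohort.

    Singleton sets (e.g. {CD274}) reduce to that gene's z-scored row.
    Absent genes are dropped with a warning; an entirely absent set is
    an error.
    """
    genes = frozenset(str(g).upper() for g in gene_set)
    present = [g for g in cohort.genes if g in genes]
    absent = genes - set(present)
    if not present:
        raise ValidationError(f"no gene of the set is present in the cohort: {sorted(genes)}")
    if absent:
        logger.warning("signature genes absent from cohort: %s", sorted(absent))
    idx = cohort.gene_index(present)
    sub = cohort.values[idx, :]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [present[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant signature genes: {bad}")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.Series(z.mean(axis=0), index=cohort.samples, name="signature_score")


@dataclass
class HybridModel:
    """A forest over merged gene-expression and signature-score features."""

    gene_features: list[str]
    signature_features: GeneSetCollection
    forest: object
    norm_mean: pd.Series
    norm_sd: pd.Series
    tier_low: float = 0.4
    tier_high: float = 0.65
    seed: int = 0
    n_trees: int = 500
    train_sample_ids: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.gene_features) + list(self.signature_features)


def _hybrid_features(model: HybridModel, cohort: ExpressionCohort) -> np.ndarray:
    cols = []
    if model.gene_features:
        idx = cohort.gene_index(model.gene_features)
        sub = cohort.values[idx, :]
        z = (sub - model.norm_mean[model.gene_features].to_numpy()[:, None]) / \
            model.norm_sd[model.gene_features].to_numpy()[:, None]
        cols.append(z.T)
    for name in model.signature_features:
        cols.append(signature_score(cohort, model.signature_features[name]).to_numpy()[:, None])
    return np.hstack(cols)


def build_hybrid(
    train: ExpressionCohort,
    gene_features: list[str],
    signature_features: GeneSetCollection,
    seed: int = 0,
    *,
    n_trees: int = 500,
    tier_low: float = 0.4,
    tier_high: float = 0.65,
) -> HybridModel:
    """Train a forest on z-scored genes merged with signature scores.

    With an empty signature collection the feature table reduces to the
    plain gene signature and the model is equivalent to
    :func:`icisig.model.train_signature` at the same seed.  A
    signatures-only model (empty gene list) is supported too.
    """
    gene_features = [g.upper() for g in gene_features]
    if not gene_features and not len(signature_features):
        raise ValidationError("empty combined feature set")
    y = train.y
    if gene_features:
        idx = train.gene_index(gene_features)
        sub = train.values[idx, :]
        mean = pd.Series(sub.mean(axis=1), index=gene_features)
        sd = pd.Series(sub.std(axis=1, ddof=1), index=gene_features)
        if (sd == 0).any():
            raise ValidationError("constant genes in training data")
    else:
        mean = pd.Series(dtype=float)
        sd = pd.Series(dtype=float)
    model = HybridModel(
        gene_features=gene_features,
        signature_features=signature_features,
        forest=None,
        norm_mean=mean,
        norm_sd=sd,
        tier_low=tier_low,
        tier_high=tier_high,
        seed=seed,
        n_trees=n_trees,
        train_sample_ids=list(train.samples),
    )
    X = _hybrid_features(model, train)
    model.forest = _fit_forest(X, y, n_trees, seed)
    return model


def score_hybrid(model: HybridModel, cohort: ExpressionCohort,
                 *, oob_for_train: bool = True) -> pd.Series:
    """Confidence scores of a hybrid model (OOB for training samples)."""
    X = _hybrid_features(model, cohort)
    col = int(np.flatnonzero(model.forest.classes_ == 1)[0])
    scores = model.forest.predict_proba(X)[:, col]
    if oob_for_train and model.train_sample_ids:
        votes = _oob_votes(model.forest)
        pos = {s: i for i, s in enumerate(model.train_sample_ids)}
        for i, s in enumerate(cohort.samples):
            if s in pos and not np.isnan(votes[pos[s]]):
                scores[i] = votes[pos[s]]
    return pd.Series(scores, index=cohort.samples, name="score")
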