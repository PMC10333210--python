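"""Iterated random-forest backward elimination of candidate genes.

The core of the classifier-construction procedure.  One elimination run
starts from the full candidate gene list, fits a random forest, ranks
the genes by importance, and repeatedly drops the least-important 20%
(rounded up) until only two genes remain, recording the out-of-bag
(OOB) vote AUC of every intermediate gene set; the set with the highest
OOB AUC is the run's best signature (ties go to the smaller set).  The
run is repeated B times (1000 in the published operating point) with
different forest seeds, and the number of runs whose best signature
contained each gene — the frequency table — measures the gene's
importance.  Finally, the AUC of nested top-k frequent-gene signatures
on held-out data locates the operating signature size.

Importance is the forest's impurity (Gini) importance by default; OOB
permutation importance is available via ``importance="oob_permutation"``
at a substantial computational cost.  Following the varSelRF
convention, the ranking is computed once on the initial forest of each
run unless ``recompute=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .io import ExpressionCohort, ValidationError


@dataclass
class EliminationTrace:
    """One backward-elimination run: nested gene sets with OOB AUCs."""

    steps: list[tuple[tuple[str, ...], float]]
    selected_index: int

    @property
    def selected_genes(self) -> tuple[str, ...]:
        return self.steps[self.selected_index][0]

    @property
    def selected_auc(self) -> float:
        return self.steps[self.selected_index][1]


@dataclass
class FrequencyTable:
    """Per-gene inclusion counts over B elimination runs.

    ``counts[g]`` is the number of runs whose best signature contained
    gene g.  ``mean_stage[g]`` is the average number of elimination
    steps before g was dropped subtracted from the trace length, i.e.
    smaller = survived longer; it breaks frequency ties.
    """

    counts: pd.Series
    mean_stage: pd.Series
    B: int

    def __post_init__(self) -> None:
        if ((self.counts < 0) | (self.counts > self.B)).any():
            raise ValidationError("counts must lie in [0, B]")

    def ordered_genes(self) -> list[str]:
        """Candidates ordered by frequency, then survival, then symbol."""
        frame = pd.DataFrame({"count": self.counts, "stage": self.mean_stage})
        frame = frame.sort_index()
        frame = frame.sort_values(["count", "stage"],
                                  ascending=[False, True], kind="stable")
        return list(frame.index)


@dataclass
class KCurve:
    """Evaluation-cohort AUC of nested top-k frequent-gene signatures."""

    entries: dict[int, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    chosen_k: int = 0

    @property
    def chosen_genes(self) -> tuple[str, ...]:
        return self.entries[self.chosen_k][0]

    @property
    def chosen_auc(self) -> float:
        return self.entries[self.chosen_k][1]


# ---------------------------------------------------------------------------


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        clf.fit(X, y)
    return clf


def _oob_votes(clf: RandomForestClassifier) -> np.ndarray:
    """Per-sample OOB responder-vote fraction (NaN if never out of bag)."""
    dec = clf.oob_decision_function_
    col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return dec[:, col]


def _oob_auc(clf: RandomForestClassifier, y: np.ndarray) -> float:
    votes = _oob_votes(clf)
    ok = ~np.isnan(votes)
    if len(set(y[ok])) < 2:
        return 0.5
    return float(roc_auc_score(y[ok], votes[ok]))


def oob_permutation_importance(
    clf: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Per-feature OOB permutation importance.

    For each tree, accuracy on its out-of-bag samples is compared
    before and after permuting one feature column; the importance is
    the mean accuracy drop over trees.
    """
    from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap

    rng = np.random.default_rng(seed)
    n_samples, n_features = X.shape
    n_boot = _get_n_samples_bootstrap(n_samples, clf.max_samples, None)
    oob_idx = [
        _generate_unsampled_indices(tree.random_state, n_samples, n_boot, None)
        for tree in clf.estimators_
    ]
    base = np.array([
        (tree.predict(X[idx]) == y[idx]).mean() if len(idx) else np.nan
        for tree, idx in zip(clf.estimators_, oob_idx)
    ])
    imp = np.zeros(n_features)
    for j in range(n_features):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        drop = np.array([
            base[t] - (tree.predict(Xp[idx]) == y[idx]).mean() if len(idx) else np.nan
            for t, (tree, idx) in enumerate(zip(clf.estimators_, oob_idx))
        ])
        imp[j] = np.nanmean(drop)
    return imp


def _next_size(m: int, drop_fraction: float) -> int:
    """Genes kept after one elimination step: ceil((1-drop)*m), floor 2.

    The ceiling keeps the 20% schedule on the canonical
    100 -> 80 -> 64 -> 52 -> ... ladder; at least one gene is always
    dropped so the recursion terminates.
    """
    nxt = math.ceil((1.0 - drop_fraction) * m)
    return max(min(nxt, m - 1), 2)


def elimination_set_sizes(m: int, drop_fraction: float) -> list[int]:
    """The gene-set sizes visited starting from m candidates."""
    sizes = [m]
    while sizes[-1] > 2:
        sizes.append(_next_size(sizes[-1], drop_fraction))
    return sizes


def rf_backward_eliminate(
    train: ExpressionCohort,
    genes: list[str],
    *,
    n_trees: int = 500,
    drop_fraction: float = 0.2,
    importance: str = "impurity",
    recompute: bool = False,
    seed: int = 0,
) -> EliminationTrace:
    """One backward-elimination run over the candidate genes.

    Keeps the ``ceil((1 - drop_fraction) * m)`` most-important genes per
    step down to two genes, recording each set's OOB-vote AUC; the
    returned trace marks the set with the maximal AUC (ties -> fewer
    genes).
    """
    if len(genes) < 2:
        raise ValidationError("need at least 2 candidate genes")
    if importance not in {"impurity", "oob_permutation"}:
        raise ValueError(f"unknown importance method {importance!r}")
    idx = train.gene_index(genes)
    y = train.y
    if len(set(y)) < 2:
        raise ValidationError("both classes must be present in the training set")
    X_full = train.X[:, idx]
    current = np.arange(len(genes))

    steps: list[tuple[tuple[str, ...], float]] = []
    imp_current: np.ndarray | None = None  # aligned with `current`
    rng = np.random.default_rng(seed)
    while True:
        sub_seed = int(rng.integers(0, 2**31))
        clf = _fit_forest(X_full[:, current], y, n_trees, sub_seed)
        steps.append((tuple(genes[i] for i in current), _oob_auc(clf, y)))
        if len(current) <= 2:
            break
        if imp_current is None:
            if importance == "impurity":
                imp_current = clf.feature_importances_
            else:
                imp_current = oob_permutation_importance(
                    clf, X_full[:, current], y, sub_seed
                )
        n_keep = _next_size(len(current), drop_fraction)
        keep_pos = np.sort(np.argsort(-imp_current, kind="stable")[:n_keep])
        current = current[keep_pos]
        imp_current = None if recompute else imp_current[keep_pos]

    best = 0
    for i, (gs, auc) in enumerate(steps):
        b_gs, b_auc = steps[best]
        if auc > b_auc or (auc == b_auc and len(gs) < len(b_gs)):
            best = i
    return EliminationTrace(steps=steps, selected_index=best)


def iterate_selection(
    train: ExpressionCohort,
    genes: list[str],
    B: int = 1000,
    master_seed: int = 0,
    *,
    bootstrap: bool = False,
    n_trees: int = 500,
    drop_fraction: float = 0.2,
    importance: str = "impurity",
    recompute: bool = False,
) -> FrequencyTable:
    """Run B elimination iterations and tally best-signature membership.

    Iterations differ by forest seed (derived from ``master_seed`` via a
    seed sequence, so the whole table is deterministic); with
    ``bootstrap=True`` each iteration additionally resamples the
    training samples with replacement.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    counts = pd.Series(0, index=sorted(genes), dtype=int)
    stage_sum = pd.Series(0.0, index=sorted(genes))
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(B)
    for b in range(B):
        child = int(children[b].generate_state(1)[0] % (2**31))
        cohort_b = train
        if bootstrap:
            rng = np.random.default_rng(child)
            for _ in range(100):
                take = rng.integers(0, train.n_samples, train.n_samples)
                if len(set(train.y[take])) == 2:
                    break
            else:
                raise ValidationError("bootstrap cannot produce both classes")
            # bootstrap duplicates samples; rebuild with unique ids
            cohort_b = ExpressionCohort(
                genes=list(train.genes),
                samples=[f"b{b}_{i}" for i in range(len(take))],
                values=train.values[:, take],
                response=train.response[take],
                batch=train.batch[take],
                cohort_id=train.cohort_id,
                treatment=train.treatment,
            )
        trace = rf_backward_eliminate(
            cohort_b, genes, n_trees=n_trees, drop_fraction=drop_fraction,
            importance=importance, recompute=recompute, seed=child,
        )
        selected = set(trace.selected_genes)
        counts[counts.index.isin(selected)] += 1
        T = len(trace.steps)
        survived = pd.Series(0, index=counts.index, dtype=int)
        for gs, _ in trace.steps:
            survived[survived.index.isin(set(gs))] += 1
        stage_sum += T - survived  # 0 = survived to the end; larger = dropped earlier
    return FrequencyTable(counts=counts, mean_stage=stage_sum / B, B=B)


def evaluate_topk(
    freq: FrequencyTable,
    train: ExpressionCohort,
    evaluation: ExpressionCohort,
    k_grid: list[int],
    *,
    n_trees: int = 500,
    seed: int = 0,
    fixed_k: int | None = None,
) -> KCurve:
    """AUC of each nested top-k frequent-gene signature on held-out data.

    A fresh forest is trained per k on the training cohort (genes in
    frequency order) and scored on the evaluation cohort, which must be
    sample-disjoint from training.  ``chosen_k`` maximizes AUC (ties ->
    smallest k) unless ``fixed_k`` pins the published signature size.
    """
    overlap = set(train.samples) & set(evaluation.samples)
    if overlap:
        raise ValidationError(f"evaluation cohort shares samples with training: {sorted(overlap)[:5]}")
    y_eval = evaluation.y
    if len(set(y_eval)) < 2:
        raise ValidationError("evaluation cohort must contain both classes")
    ordered = freq.ordered_genes()
    if any(k < 1 or k > len(ordered) for k in k_grid):
        raise ValidationError("k_grid values must lie in [1, #candidates]")
    y_train = train.y
    entries: dict[int, tuple[tuple[str, ...], float]] = {}
    for k in sorted(set(k_grid)):
        genes_k = ordered[:k]
        Xtr = train.X[:, train.gene_index(genes_k)]
        Xev = evaluation.X[:, evaluation.gene_index(genes_k)]
        clf = _fit_forest(Xtr, y_train, n_trees, seed)
        col = int(np.flatnonzero(clf.classes_ == 1)[0])
        scores = clf.predict_proba(Xev)[:, col]
        entries[k] = (tuple(genes_k), float(roc_auc_score(y_eval, scores)))
    if fixed_k is not None:
        if fixed_k not in entries:
            raise ValidationError("fixed_k must be one of the evaluated k values")
        chosen = fixed_k
    else:
        chosen = min(entries, key=lambda k: (-entries[k][1], k))
    return KCurve(entries=entries, chosen_k=chosen)
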