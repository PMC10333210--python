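"""Batch correction, per-gene z-normalization and stratified splitting.

The correction removes location/scale differences between treatment
arms (e.g. the durvalumab and pembrolizumab arms of a platform trial)
before cohorts are pooled.  Two modes are offered:

``eb``
    Parametric empirical-Bayes location/scale adjustment (ComBat) with
    no covariates, delegated to :func:`scanpy.pp.combat`.
``exact``
    The same standardize / per-batch adjust / restore algebra without
    the EB shrinkage step, which makes the result checkable in closed
    form (two batches differing by a constant per-gene shift come out
    with equal per-batch means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NON_RESPONDER, RESPONDER, ExpressionCohort, ValidationError

logger = logging.getLogger("icisig")


@dataclass
class SplitResult:
    """A stratified train/validation partition of a cohort."""

    train: ExpressionCohort
    validation: ExpressionCohort
    seed: int


def zscore_by_gene(
    cohort: ExpressionCohort, return_stats: bool = False
) -> ExpressionCohort | tuple[ExpressionCohort, pd.DataFrame]:
    """Normalize each gene to sample mean 0, SD 1 (n-1 denominator).

    Constant genes are dropped with a warning.  With
    ``return_stats=True`` also returns the per-gene mean/SD table so an
    external cohort can later be projected with training-set parameters.
    """
    vals = cohort.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(cohort.genes, keep) if not k]
        logger.warning("dropping %d constant genes: %s", len(dropped), dropped[:5])
    z = (vals[keep] - mean[keep, None]) / sd[keep, None]
    out = ExpressionCohort(
        genes=[g for g, k in zip(cohort.genes, keep) if k],
        samples=list(cohort.samples),
        values=z,
        response=cohort.response.copy(),
        batch=cohort.batch.copy(),
        cohort_id=cohort.cohort_id,
        treatment=cohort.treatment,
    )
    if return_stats:
        stats = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]}, index=out.genes)
        return out, stats
    return out


def correct_batch(cohort: ExpressionCohort, method: str = "eb") -> ExpressionCohort:
    """Remove per-batch location/scale effects from the expression matrix.

    A single-batch cohort is returned unchanged.  Genes with zero
    variance within some batch are dropped with a warning.  ``method``
    is ``eb`` (ComBat parametric empirical Bayes) or ``exact``
    (shrinkage-free closed-form adjustment).
    """
    if method not in {"eb", "exact"}:
        raise ValueError(f"unknown batch-correction method {method!r}")
    batches = pd.unique(cohort.batch)
    if len(batches) < 2:
        return cohort.copy()
    counts = pd.Series(cohort.batch).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"batches with fewer than 2 samples: {list(small.index)}")

    # drop genes constant within any batch: their scale is unestimable
    keep = np.ones(cohort.n_genes, dtype=bool)
    for b in batches:
        cols = cohort.batch == b
        keep &= cohort.values[:, cols].std(axis=1, ddof=1) > 0
    if not keep.all():
        dropped = [g for g, k in zip(cohort.genes, keep) if not k]
        logger.warning(
            "dropping %d genes with zero within-batch variance: %s",
            len(dropped), dropped[:5],
        )
        cohort = cohort.subset_genes([g for g, k in zip(cohort.genes, keep) if k])

    if method == "eb":
        corrected = _combat_eb(cohort)
    else:
        corrected = _combat_exact(cohort)
    out = cohort.copy()
    out.values = corrected
    return out


def _combat_eb(cohort: ExpressionCohort) -> np.ndarray:
    import anndata
    import scanpy as sc

    adata = anndata.AnnData(
        X=cohort.X.astype(np.float64),
        obs=pd.DataFrame({"batch": pd.Categorical(cohort.batch)},
                         index=cohort.samples),
    )
    sc.pp.combat(adata, key="batch")
    return np.asarray(adata.X).T


def _combat_exact(cohort: ExpressionCohort) -> np.ndarray:
    """Location/scale batch adjustment without EB shrinkage.

    Standardize each gene with its grand mean and pooled SD, estimate
    each batch's gene-wise mean and SD on the standardized data, remove
    them, then restore the grand location/scale.
    """
    X = cohort.values
    grand_mean = X.mean(axis=1)
    pooled_sd = X.std(axis=1, ddof=1)
    Z = (X - grand_mean[:, None]) / pooled_sd[:, None]
    out = np.empty_like(Z)
    for b in pd.unique(cohort.batch):
        cols = cohort.batch == b
        gamma = Z[:, cols].mean(axis=1)
        delta = Z[:, cols].std(axis=1, ddof=1)
        out[:, cols] = (Z[:, cols] - gamma[:, None]) / delta[:, None]
    return out * pooled_sd[:, None] + grand_mean[:, None]


def stratified_split(
    cohort: ExpressionCohort, train_fraction: float = 0.6, seed: int = 0
) -> SplitResult:
    """Split a cohort into train/validation parts, stratified by response.

    Within each response class the samples are shuffled and a counted
    take of ``round(train_fraction * n_class)`` goes to training, so the
    responder proportion of each part tracks the whole cohort to within
    one sample.  Deterministic under a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in (RESPONDER, NON_RESPONDER):
        pos = np.flatnonzero(cohort.response == cls)
        if len(pos) < 2:
            raise ValidationError(
                f"class {cls} has {len(pos)} samples; cannot appear in both parts"
            )
        rng.shuffle(pos)
        n_train = int(round(train_fraction * len(pos)))
        n_train = min(max(n_train, 1), len(pos) - 1)
        train_idx.extend(pos[:n_train])
        val_idx.extend(pos[n_train:])
    other = np.flatnonzero(
        ~np.isin(cohort.response, [RESPONDER, NON_RESPONDER])
    )
    if len(other):
        raise ValidationError("cannot split a cohort with unknown response labels")
    return SplitResult(
        train=cohort.subset_samples(sorted(train_idx)),
        validation=cohort.subset_samples(sorted(val_idx)),
        seed=seed,
    )
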