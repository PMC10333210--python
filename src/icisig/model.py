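"""The final signature classifier: training, confidence scores, tiers.

A :class:`SignatureModel` is a random forest fit on the z-normalized
expression of a fixed, ordered gene list (e.g. a 37-gene signature
derived by :mod:`icisig.featsel`).  Its per-sample output is a
confidence score in [0, 1] — the fraction of trees voting "responder" —
rather than a dichotomous call; for samples that were part of the
training set only out-of-bag trees vote, keeping the score unbiased.
Scores at or below ``tier_low`` (0.4) mark reliable non-responders,
scores at or over ``tier_high`` (0.65) reliable responders, and
anything strictly between is uncertain.

External cohorts are scored by projecting their expression with the
training-set normalization statistics (mean/SD per gene frozen at fit
time); per-cohort re-normalization is available as an explicit option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featsel import _fit_forest, _oob_votes
from .io import ExpressionCohort, FormatError, ValidationError

RELIABLE_NON_RESPONDER = "reliable_non_responder"
UNCERTAIN = "uncertain"
RELIABLE_RESPONDER = "reliable_responder"

_BUNDLE_VERSION = 1


@dataclass
class SignatureModel:
    """A trained signature forest with its normalization statistics."""

    genes: list[str]
    forest: object
    norm_mean: pd.Series
    norm_sd: pd.Series
    tier_low: float = 0.4
    tier_high: float = 0.65
    seed: int = 0
    n_trees: int = 500
    train_sample_ids: list[str] = field(default_factory=list)
    train_X_z: np.ndarray | None = None  # samples x genes, z-space
    train_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene list contains duplicates")
        if not 0 <= self.tier_low < self.tier_high <= 1:
            raise ValidationError("tier cutoffs must satisfy 0 <= low < high <= 1")
        for g in self.genes:
            if g not in self.norm_mean.index or g not in self.norm_sd.index:
                raise ValidationError(f"normalization statistics missing for {g}")

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": _BUNDLE_VERSION,
            "genes": list(self.genes),
            "norm_mean": [float(self.norm_mean[g]) for g in self.genes],
            "norm_sd": [float(self.norm_sd[g]) for g in self.genes],
            "tier_low": self.tier_low,
            "tier_high": self.tier_high,
            "seed": self.seed,
            "n_trees": self.n_trees,
            "train_sample_ids": list(self.train_sample_ids),
            "train_X_z": np.asarray(self.train_X_z).tolist(),
            "train_labels": np.asarray(self.train_labels).tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SignatureModel":
        if data.get("version") != _BUNDLE_VERSION:
            raise FormatError(
                f"model bundle version {data.get('version')!r} != {_BUNDLE_VERSION}"
            )
        genes = list(data["genes"])
        X = np.asarray(data["train_X_z"], dtype=float)
        y = np.asarray(data["train_labels"], dtype=int)
        forest = _fit_forest(X, y, int(data["n_trees"]), int(data["seed"]))
        return cls(
            genes=genes,
            forest=forest,
            norm_mean=pd.Series(data["norm_mean"], index=genes, dtype=float),
            norm_sd=pd.Series(data["norm_sd"], index=genes, dtype=float),
            tier_low=float(data["tier_low"]),
            tier_high=float(data["tier_high"]),
            seed=int(data["seed"]),
            n_trees=int(data["n_trees"]),
            train_sample_ids=list(data["train_sample_ids"]),
            train_X_z=X,
            train_labels=y,
        )


def train_signature(
    train: ExpressionCohort,
    genes: list[str],
    seed: int = 0,
    *,
    n_trees: int = 500,
    tier_low: float = 0.4,
    tier_high: float = 0.65,
) -> SignatureModel:
    """Fit the signature forest on the z-normalized gene submatrix.

    Normalization statistics (per-gene mean and n-1 SD) are frozen from
    the training cohort.  Deterministic under a fixed seed.
    """
    genes = [g.upper() for g in genes]
    idx = train.gene_index(genes)  # raises naming missing symbols
    y = train.y
    if len(set(y)) < 2:
        raise ValidationError("training cohort must contain both classes")
    sub = train.values[idx, :]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValidationError(f"constant genes in training data: {bad}")
    Xz = ((sub - mean[:, None]) / sd[:, None]).T
    forest = _fit_forest(Xz, y, n_trees, seed)
    return SignatureModel(
        genes=genes,
        forest=forest,
        norm_mean=pd.Series(mean, index=genes),
        norm_sd=pd.Series(sd, index=genes),
        tier_low=tier_low,
        tier_high=tier_high,
        seed=seed,
        n_trees=n_trees,
        train_sample_ids=list(train.samples),
        train_X_z=Xz,
        train_labels=y,
    )


def _responder_col(forest) -> int:
    return int(np.flatnonzero(forest.classes_ == 1)[0])


def _project(model: SignatureModel, cohort: ExpressionCohort,
             missing_policy: str = "error", renormalize: bool = False) -> np.ndarray:
    """Cohort expression -> z-space feature matrix over the model's genes."""
    present = set(cohort.genes)
    missing = [g for g in model.genes if g not in present]
    if missing and missing_policy == "error":
        raise ValidationError(f"model genes missing from cohort: {missing}")
    n = cohort.n_samples
    X = np.zeros((n, len(model.genes)))
    for j, g in enumerate(model.genes):
        if g in present:
            row = cohort.values[cohort.genes.index(g), :]
            if renormalize:
                sd = row.std(ddof=1)
                if sd == 0:
                    raise ValidationError(f"gene {g} constant in cohort; cannot re-normalize")
                X[:, j] = (row - row.mean()) / sd
            else:
                X[:, j] = (row - model.norm_mean[g]) / model.norm_sd[g]
        # missing gene under impute_zero: stays at the training mean in z-space
    if missing:
        warnings.warn(f"imputed {len(missing)} missing model genes at z = 0: {missing}")
    return X


def score_samples(
    model: SignatureModel, cohort: ExpressionCohort, *, oob_for_train: bool = True
) -> pd.DataFrame:
    """Confidence score per sample: fraction of trees voting responder.

    Samples that belong to the model's training set are scored with
    out-of-bag trees only (flagged in the ``oob`` column) unless
    ``oob_for_train=False`` requests all-trees scores throughout.
    """
    X = _project(model, cohort)
    col = _responder_col(model.forest)
    scores = model.forest.predict_proba(X)[:, col]
    oob_flag = np.zeros(cohort.n_samples, dtype=bool)
    if oob_for_train and model.train_sample_ids:
        votes = _oob_votes(model.forest)
        pos = {s: i for i, s in enumerate(model.train_sample_ids)}
        for i, s in enumerate(cohort.samples):
            if s in pos and not np.isnan(votes[pos[s]]):
                scores[i] = votes[pos[s]]
                oob_flag[i] = True
    return pd.DataFrame({"score": scores, "oob": oob_flag}, index=cohort.samples)


def categorize(score) -> str | np.ndarray:
    """Map a confidence score to its reliability tier.

    <= tier_low (0.4): reliable non-responder; >= tier_high (0.65):
    reliable responder; strictly between: uncertain.  Accepts scalars
    or arrays; tier cutoffs beyond the defaults come from the model.
    """
    return categorize_with(score, 0.4, 0.65)


def categorize_with(score, tier_low: float, tier_high: float):
    arr = np.asarray(score, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("confidence scores must lie in [0, 1]")
    tiers = np.where(
        arr <= tier_low,
        RELIABLE_NON_RESPONDER,
        np.where(arr >= tier_high, RELIABLE_RESPONDER, UNCERTAIN),
    )
    return str(tiers[()]) if np.ndim(score) == 0 else tiers


def apply_cross_cohort(
    model: SignatureModel,
    external: ExpressionCohort,
    missing_policy: str = "error",
    *,
    renormalize: bool = False,
) -> pd.Series:
    """Score an external cohort with the frozen training normalization.

    ``missing_policy`` is ``error`` (abort listing missing symbols) or
    ``impute_zero`` (missing genes sit at the training mean, i.e. 0 in
    z-space).  ``renormalize=True`` re-standardizes each gene within
    the external cohort instead of projecting with training statistics.
    """
    if missing_policy not in {"error", "impute_zero"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    X = _project(model, external, missing_policy, renormalize)
    col = _responder_col(model.forest)
    scores = model.forest.predict_proba(X)[:, col]
    return pd.Series(scores, index=external.samples, name="score")
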