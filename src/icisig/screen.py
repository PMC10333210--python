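"""Pan-cancer gene meta-scoring across ICI-treated cohorts.

Candidate response genes are screened across a panel of cohorts of
ICI-plus-chemotherapy-treated patients.  Within each cohort every gene
gets a signed score

    s_gc = -log10(p_gc) * log2(n_c)

where ``p_gc`` is the Student's t p-value for responders versus
non-responders and ``n_c`` the cohort size; the score is negated for
genes downregulated in responders.  Per-gene scores are summed over
cohorts (a gene missing from a cohort contributes 0 there) and the
genes with the largest absolute aggregate score become the candidate
feature pool for classifier construction (top 500 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import DOWN, UP, t_test_by_gene
from .io import ExpressionCohort, ValidationError

logger = logging.getLogger("icisig")

_P_FLOOR = np.finfo(float).tiny  # clamp for p-value underflow


@dataclass
class CohortDEResult:
    """Per-cohort differential test summary feeding the meta-score."""

    cohort_id: str
    n: int
    p: pd.Series          # per-gene two-sided t p-value
    direction: pd.Series  # per-gene, up_in_responders / down_in_responders

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValidationError("cohort must have >= 4 patients (>= 2 per class)")
        if not self.p.index.equals(self.direction.index):
            raise ValidationError("p and direction must be indexed by the same genes")
        if ((self.p <= 0) | (self.p > 1)).any():
            raise ValidationError("p-values must lie in (0, 1]")


@dataclass
class PanCancerScoreTable:
    """Per-gene per-cohort scores with their aggregate and rank.

    ``scores`` holds one column per cohort (NaN where the gene is not
    measured), plus ``score`` (the aggregate S_g) and ``rank``
    (1 = largest |S_g|; ties broken by symbol order).
    """

    scores: pd.DataFrame

    @property
    def aggregate(self) -> pd.Series:
        return self.scores["score"]


def cohort_gene_score(p, n: int, direction) -> float | np.ndarray:
    """Signed cohort score: ``(-log10 p) * log2(n)``, negative for down genes.

    Accepts scalars or aligned arrays for ``p`` and ``direction``.
    p = 0 is clamped to the smallest positive float with a warning.
    """
    if n < 2:
        raise ValidationError("cohort size must be >= 2")
    p_arr = np.asarray(p, dtype=float)
    if (p_arr < 0).any() or (p_arr > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    if (p_arr == 0).any():
        warnings.warn("p-value underflow clamped to smallest positive float")
        p_arr = np.where(p_arr == 0, _P_FLOOR, p_arr)
    sign = np.where(np.asarray(direction) == DOWN, -1.0, 1.0)
    s = -np.log10(p_arr) * np.log2(n) * sign
    return float(s) if np.isscalar(p) or np.ndim(p) == 0 else s


def de_result_from_cohort(cohort: ExpressionCohort) -> CohortDEResult:
    """Run the per-gene pooled t-test and record direction from the t sign."""
    tt = t_test_by_gene(cohort)
    direction = pd.Series(np.where(tt["t"] > 0, UP, DOWN), index=tt.index)
    p = tt["p"].clip(lower=_P_FLOOR)
    return CohortDEResult(
        cohort_id=cohort.cohort_id, n=cohort.n_samples, p=p, direction=direction
    )


def aggregate_panel(results: list[CohortDEResult]) -> PanCancerScoreTable:
    """Sum signed cohort scores per gene over the panel.

    Gene universes may differ between cohorts; an unmeasured (gene,
    cohort) pair contributes 0 to the aggregate rather than excluding
    the gene.
    """
    if not results:
        raise ValidationError("empty panel")
    cols = {}
    for r in results:
        s = cohort_gene_score(r.p.to_numpy(), r.n, r.direction.to_numpy())
        cols[r.cohort_id] = pd.Series(s, index=r.p.index)
    frame = pd.DataFrame(cols)
    frame["score"] = frame.fillna(0.0).sum(axis=1)
    # stable sort on a symbol-sorted frame = ties broken lexicographically
    frame = frame.sort_index()
    order = frame["score"].abs().sort_values(ascending=False, kind="stable")
    frame["rank"] = pd.Series(
        np.arange(1, len(frame) + 1), index=order.index
    ).reindex(frame.index)
    return PanCancerScoreTable(scores=frame)


def select_top_scored(table: PanCancerScoreTable, k: int = 500) -> list[str]:
    """The k genes with the largest |aggregate score|.

    Ties are broken by lexicographic symbol order; ``k`` larger than
    the gene universe returns every gene.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    frame = table.scores.sort_index()
    order = frame["score"].abs().sort_values(ascending=False, kind="stable")
    return list(order.index[:k])
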