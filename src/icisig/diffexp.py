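"""Per-gene two-group testing and the Z-ratio differential call.

A gene is called differentially expressed between responders and
non-responders when its pooled-variance Student's t-test p-value is
strictly below ``p_threshold`` (default 0.05) and its absolute Z-ratio
is strictly above ``zratio_threshold`` (default 1.5).  No
multiple-testing correction is applied: the published operating point
uses raw p-values, and this module reproduces it faithfully.

The Z-ratio follows the Cheadle convention: each sample's expression is
z-transformed across genes, the responder minus non-responder mean
difference of these z-values is computed per gene, and that difference
is scaled by its own standard deviation across all genes.  Under the
null the Z-ratio is standard normal over genes, so |Z-ratio| > 1.5
marks roughly the 13.4% most extreme genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionCohort, ValidationError

UP = "up_in_responders"
DOWN = "down_in_responders"


@dataclass
class DEGene:
    symbol: str
    t: float
    p: float
    z_ratio: float
    direction: str
    is_de: bool


def student_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-sided.

    The t statistic carries the sign of ``mean(a) - mean(b)``.  Groups
    with zero pooled variance return (0.0, 1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)


def t_test_by_gene(cohort: ExpressionCohort) -> pd.DataFrame:
    """Vectorized pooled t-test for every gene: columns ``t`` and ``p``.

    Zero-pooled-variance genes are flagged (t = 0, p = 1).
    """
    y = cohort.y
    a = cohort.values[:, y == 1]
    b = cohort.values[:, y == 0]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each class needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"t": t, "p": p}, index=cohort.genes)


def z_ratio(cohort: ExpressionCohort) -> pd.Series:
    """Per-gene Z-ratio between responders and non-responders.

    Each sample is z-transformed across genes; the per-gene group mean
    difference of the z-values is divided by the SD of that difference
    over all genes, so the Z-ratios themselves have SD 1 by
    construction.
    """
    if cohort.n_genes < 2:
        raise ValidationError("Z-ratio needs at least 2 genes")
    y = cohort.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("each class needs at least 2 samples")
    vals = cohort.values
    col_mean = vals.mean(axis=0)
    col_sd = vals.std(axis=0, ddof=1)
    if (col_sd == 0).any():
        raise ValidationError("sample with zero expression variance across genes")
    z = (vals - col_mean[None, :]) / col_sd[None, :]
    diff = z[:, y == 1].mean(axis=1) - z[:, y == 0].mean(axis=1)
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate cohort: all genes share one group difference")
    return pd.Series(diff / sd, index=cohort.genes, name="z_ratio")


def call_differential(
    cohort: ExpressionCohort,
    p_threshold: float = 0.05,
    zratio_threshold: float = 1.5,
) -> pd.DataFrame:
    """Differential-expression call for every gene.

    Returns a frame indexed by gene with columns ``t``, ``p``,
    ``z_ratio``, ``direction`` and ``is_de``.  Both thresholds are
    strict inequalities (p exactly at the threshold is not called), and
    direction is taken from the sign of the Z-ratio.
    """
    tt = t_test_by_gene(cohort)
    zr = z_ratio(cohort)
    out = tt.assign(z_ratio=zr)
    out["direction"] = np.where(out["z_ratio"] > 0, UP, DOWN)
    out["is_de"] = (out["p"] < p_threshold) & (out["z_ratio"].abs() > zratio_threshold)
    return out


def de_genes(table: pd.DataFrame) -> list[DEGene]:
    """The rows of a :func:`call_differential` frame as typed records."""
    return [
        DEGene(symbol=g, t=row.t, p=row.p, z_ratio=row.z_ratio,
               direction=row.direction, is_de=bool(row.is_de))
        for g, row in table.iterrows()
    ]
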