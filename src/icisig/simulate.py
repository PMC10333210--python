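"""Synthetic cohort generator with planted response-predictive genes.

The generator emulates the statistical structure the pipeline assumes in
real neoadjuvant ICI-plus-chemotherapy cohorts: Gaussian per-gene
baseline expression on the log2 scale, a binary responder (pCR) label
with configurable prevalence, a minority of signal genes carrying an
additive mean shift between responders and non-responders, and per-arm
batch location/scale effects.  Every downstream stage of the pipeline is
testable against the planted ground truth without any data download.

Model for sample i, gene g::

    x_ig = mu_g + b_{g, batch(i)} + 1[i responder] * delta_g * sigma_g
           + eps_ig,        eps_ig ~ Normal(0, sigma_g * m_{batch(i)})

where ``delta_g`` is the signed effect in units of the per-gene SD
(nonzero only on signal genes), ``b`` are per-gene batch location shifts
drawn Normal(0, tau_loc) and ``m`` are per-batch noise-scale factors
exp(Normal(0, tau_scale)).  Batch assignment is stratified by response,
so batch and response are unconfounded by construction.

Responder counts are exact: round(n * response_rate) samples (clipped to
leave at least two per class) are labelled responders and positions are
randomly permuted, which pins the prevalence to within one sample of its
target while keeping the draw fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import NON_RESPONDER, RESPONDER, ExpressionCohort, ValidationError


@dataclass
class SimulationDesign:
    """Parameters of one simulated cohort.

    ``effect_size`` (delta) is the mean shift on signal genes in units of
    the per-gene SD; ``direction_mix`` is the fraction of signal genes
    upregulated in responders.  Baseline means are Normal(7, 1.5) and
    baseline SDs |Normal(0.6, 0.2)| + 0.2, typical of log2 array data.
    Batch effects default to off; scenarios that exercise batch
    correction switch them on explicitly.
    """

    n_genes: int = 1000
    n_signal: int = 30
    n_samples: int = 100
    response_rate: float = 0.5
    effect_size: float = 1.0
    direction_mix: float = 0.5
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    batch_scale_sd: float = 0.0
    baseline_mean: tuple[float, float] = (7.0, 1.5)
    baseline_sd: tuple[float, float] = (0.6, 0.2)
    seed: int | None = None
    cohort_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_signal > self.n_genes:
            raise ValidationError("n_signal cannot exceed n_genes")
        if not 0 < self.response_rate < 1:
            raise ValidationError("response_rate must lie strictly in (0, 1)")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples (2 per class)")
        if self.n_batches < 1:
            raise ValidationError("need at least one batch")


@dataclass
class SimulatedTruth:
    """Planted ground truth: which genes carry signal and how much.

    ``effects`` maps gene symbol -> signed effect in per-gene-SD units
    (positive = upregulated in responders); nonzero exactly on the
    signal genes.
    """

    signal_genes: list[str] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.signal_genes) != set(self.effects):
            raise ValidationError("signal gene list and effect map disagree")
        if any(v == 0 for v in self.effects.values()):
            raise ValidationError("signal genes must carry nonzero effects")


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def _draw_truth(design: SimulationDesign, genes: list[str], rng: np.random.Generator) -> SimulatedTruth:
    if design.n_signal == 0:
        return SimulatedTruth()
    idx = rng.choice(design.n_genes, size=design.n_signal, replace=False)
    n_up = int(round(design.n_signal * design.direction_mix))
    signs = np.array([1.0] * n_up + [-1.0] * (design.n_signal - n_up))
    rng.shuffle(signs)
    effects = {genes[i]: float(s * design.effect_size) for i, s in zip(idx, signs)}
    return SimulatedTruth(signal_genes=[genes[i] for i in sorted(idx)], effects=effects)


def simulate_cohort(
    design: SimulationDesign,
    seed: int | None = None,
    *,
    truth: SimulatedTruth | None = None,
    effect_scale: float = 1.0,
) -> tuple[ExpressionCohort, SimulatedTruth]:
    """Draw one cohort; identical ``(design, seed)`` gives identical output.

    ``truth`` imposes a pre-drawn signal set (used by
    :func:`simulate_screen_panel` to share signal across cohorts);
    ``effect_scale`` multiplies its effects for that cohort.
    """
    if seed is None:
        seed = design.seed
    if seed is None:
        raise ValidationError("a seed is required (argument or design.seed)")
    rng = np.random.default_rng(seed)
    G, n = design.n_genes, design.n_samples
    genes = gene_universe(G)
    samples = [f"{design.cohort_id}_S{i:04d}" for i in range(n)]

    mu = rng.normal(design.baseline_mean[0], design.baseline_mean[1], G)
    sigma = np.abs(rng.normal(design.baseline_sd[0], design.baseline_sd[1], G)) + 0.2

    # exact responder count, clipped so both classes keep >= 2 samples
    n_resp = int(round(n * design.response_rate))
    n_resp = min(max(n_resp, 2), n - 2)
    labels = np.array([RESPONDER] * n_resp + [NON_RESPONDER] * (n - n_resp), dtype=object)
    rng.shuffle(labels)

    # batch assignment stratified by response: round-robin within class
    batch_idx = np.zeros(n, dtype=int)
    for cls in (RESPONDER, NON_RESPONDER):
        pos = np.flatnonzero(labels == cls)
        rng.shuffle(pos)
        batch_idx[pos] = np.arange(len(pos)) % design.n_batches
    if design.n_batches > 1:
        counts = np.bincount(batch_idx, minlength=design.n_batches)
        if (counts < 2).any():
            raise ValidationError("a batch would receive fewer than 2 samples")

    if truth is None:
        truth = _draw_truth(design, genes, rng)
    delta = np.zeros(G)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, eff in truth.effects.items():
        if g not in gene_pos:
            raise ValidationError(f"truth gene {g} outside simulated universe")
        delta[gene_pos[g]] = eff * effect_scale

    b_loc = (
        rng.normal(0.0, design.batch_shift_sd, (G, design.n_batches))
        if design.batch_shift_sd > 0
        else np.zeros((G, design.n_batches))
    )
    m_batch = (
        np.exp(rng.normal(0.0, design.batch_scale_sd, design.n_batches))
        if design.batch_scale_sd > 0
        else np.ones(design.n_batches)
    )

    resp_mask = (labels == RESPONDER).astype(float)
    eps = rng.normal(0.0, 1.0, (G, n)) * sigma[:, None] * m_batch[batch_idx][None, :]
    values = (
        mu[:, None]
        + b_loc[:, batch_idx]
        + delta[:, None] * sigma[:, None] * resp_mask[None, :]
        + eps
    )

    cohort = ExpressionCohort(
        genes=genes,
        samples=samples,
        values=values,
        response=labels,
        batch=np.array([f"batch{b}" for b in batch_idx], dtype=object),
        cohort_id=design.cohort_id,
        treatment="ICI+chemo",
    )
    return cohort, truth


def simulate_null_cohort(design: SimulationDesign, seed: int | None = None) -> ExpressionCohort:
    """A cohort whose labels are independent of expression.

    Emulates a control population (e.g. chemotherapy-only treated
    patients) on which a response classifier should be uninformative.
    """
    cohort, _ = simulate_cohort(replace(design, n_signal=0), seed)
    return cohort


def panel_child_seed(seed: int, index: int) -> int:
    """Deterministic per-cohort seed for :func:`simulate_screen_panel`."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def simulate_screen_panel(
    designs: Sequence[SimulationDesign],
    shared_signal: SimulatedTruth | None,
    seed: int,
    cohort_factors: Sequence[float] | None = None,
) -> list[tuple[ExpressionCohort, SimulatedTruth]]:
    """Simulate several cohorts planting a shared signal-gene set.

    All designs must share one gene universe (equal ``n_genes``).  Each
    cohort carries the shared signal with its effect multiplied by the
    cohort factor (default 1.0).  With ``shared_signal=None`` each
    cohort draws its own private signal per its design, and a panel of
    one design reduces exactly to :func:`simulate_cohort` run with
    :func:`panel_child_seed`.
    """
    if not designs:
        raise ValidationError("empty panel")
    n_genes = designs[0].n_genes
    if any(d.n_genes != n_genes for d in designs):
        raise ValidationError("all panel designs must share one gene universe")
    if cohort_factors is None:
        cohort_factors = [1.0] * len(designs)
    if len(cohort_factors) != len(designs):
        raise ValidationError("one cohort factor per design required")
    if shared_signal is not None:
        universe = set(gene_universe(n_genes))
        outside = set(shared_signal.signal_genes) - universe
        if outside:
            raise ValidationError(f"shared signal outside gene universe: {sorted(outside)[:5]}")

    out = []
    for c, (design, factor) in enumerate(zip(designs, cohort_factors)):
        child = panel_child_seed(seed, c)
        design_c = replace(design, cohort_id=f"{design.cohort_id}{c}")
        cohort, truth = simulate_cohort(
            design_c, child, truth=shared_signal, effect_scale=factor
        )
        out.append((cohort, truth))
    return out
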