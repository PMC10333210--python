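import warnings

import numpy as np
import pytest

from icisig import (ExpressionCohort, SimulationDesign, simulate_cohort,
                    stratified_split, zscore_by_gene)

# forests with few trees legitimately leave some samples without OOB votes
warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cohort(rng):
    """10 genes x 12 samples, labels attached, no planted signal."""
    values = rng.normal(7, 1, size=(10, 12))
    response = np.array(["responder"] * 6 + ["non_responder"] * 6, dtype=object)
    return ExpressionCohort(
        genes=[f"GENE{i}" for i in range(10)],
        samples=[f"S{i}" for i in range(12)],
        values=values,
        response=response,
        batch=np.array(["arm_a", "arm_b"] * 6, dtype=object),
        cohort_id="toy",
    )


@pytest.fixture(scope="session")
def signal_split():
    """A z-normalized simulated signal cohort split 60/40 (session-wide)."""
    design = SimulationDesign(n_genes=300, n_signal=15, n_samples=120,
                              effect_size=1.5)
    cohort, truth = simulate_cohort(design, seed=7)
    split = stratified_split(zscore_by_gene(cohort), 0.6, seed=7)
    return split, truth
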