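import numpy as np
import pytest

from rareburden import (
    CohortTable,
    SimulationConfig,
    simulate_cohort,
)
from rareburden.association import N_PCS


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-gene cohort shared by read-only tests."""
    return simulate_cohort(
        SimulationConfig(n_subjects=2000, n_genes=2, missing_rate=0.02, seed=11)
    )


def random_cohort(rng: np.random.Generator, n: int) -> CohortTable:
    """Cohort with Bernoulli(0.3) phenotype and pure-noise covariates."""
    sex = rng.integers(0, 2, n).astype(float)
    pcs = rng.standard_normal((n, N_PCS))
    phenotype = (rng.random(n) < 0.3).astype(int)
    return CohortTable(
        [f"S{i}" for i in range(n)], phenotype, np.column_stack([sex, pcs])
    )
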