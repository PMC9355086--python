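import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import exoskat as ek

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: One seed for every fixture that needs fixed randomness.
SUITE_SEED = 20260921


@pytest.fixture(scope="session")
def standard_cohort():
    """The documented standard synthetic cohort (fixed seed)."""
    cfg = ek.standard_cohort_config(seed=SUITE_SEED)
    cohort, truth = ek.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def standard_discovery(standard_cohort):
    """Full discovery run on the standard cohort, shared across tests."""
    cohort, truth = standard_cohort
    return ek.run_discovery(cohort), truth


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for fast unit tests (all-null architectures)."""
    cfg = ek.SimConfig(
        n_samples=600,
        n_genes=8,
        variants_per_gene=(6, 10),
        chrom_layout=(("1", 500_000), ("2", 500_000)),
        seed=SUITE_SEED,
    )
    return ek.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
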