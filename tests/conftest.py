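import numpy as np
import pytest

from brcameth import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort shared by read-only tests."""
    cfg = SimConfig(
        n_brca1=12, n_brcax=12, n_test=8, n_probes=400,
        n_mut_probes=8, n_er_probes=40, n_grade_probes=3,
        mut_effect_range=(0.15, 0.30), seed=5,
    )
    beta, records, truth = generate_cohort(cfg)
    return cfg, beta, records, truth


@pytest.fixture(scope="session")
def separable_cohort():
    """A cohort with large planted effects, for clustering/prediction tests."""
    cfg = SimConfig(
        n_brca1=20, n_brcax=20, n_test=20, n_probes=600,
        n_mut_probes=15, n_er_probes=60, n_grade_probes=3,
        mut_effect_range=(0.20, 0.30), seed=17,
    )
    beta, records, truth = generate_cohort(cfg)
    return cfg, beta, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
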