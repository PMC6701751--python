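import numpy as np
import pytest

from neurotraits.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (40 subjects, 30 nodes) for fast pipeline tests."""
    cfg = CohortConfig(n_subjects=40, n_nodes=30, planted_edges_per_trait=5,
                       edge_effect=0.6, seed=1)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def large_questionnaire_cohort():
    """Large-n questionnaires for asymptotic recovery checks."""
    cfg = CohortConfig(n_subjects=2000, seed=11)
    from neurotraits.simulate import generate_questionnaires

    subscales, factors = generate_questionnaires(cfg)
    return cfg, subscales, factors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
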