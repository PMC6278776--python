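import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from somamosaic import AlleleSample, CohortSpec, SimulationConfig, StudyCohortSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sample(sizes, patient_id="P1", tissue="blood", timepoint="t1",
                age=40.0):
    return AlleleSample(
        patient_id=patient_id, tissue=tissue, timepoint=timepoint,
        age_at_sampling=age, sizes=np.asarray(sizes, dtype=float),
    )


@pytest.fixture
def sample_factory():
    return make_sample


@pytest.fixture(scope="session")
def fast_sim():
    """Reduced-scale simulation profile for Monte-Carlo-heavy tests."""
    return SimulationConfig(n_lineages=60, target_alleles=80,
                            poisson_lambda=8.0, seed=0)


@pytest.fixture(scope="session")
def fast_cohort_spec():
    """Reduced-size reference cohort for Monte-Carlo-heavy tests."""
    return CohortSpec(n_subjects=30, n_symptomatic=27)


@pytest.fixture(scope="session")
def fast_study_spec():
    return StudyCohortSpec(n_buccal_interrupted=2, n_buccal_control=1)


@pytest.fixture(scope="session")
def default_sim():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_cohort_spec():
    return CohortSpec()
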