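import pytest
from hypothesis import HealthCheck, settings

from comorbindex import build_outcomes, build_profiles, generate_cohort
from comorbindex.index_builder import assign_levels, published_model, score_profiles
from comorbindex.synthetic_cohort import ScenarioConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """Moderate synthetic cohort under the default (cohort-emulation) scenario."""
    return generate_cohort(ScenarioConfig(n_patients=4000, seed=11))


@pytest.fixture(scope="session")
def profiles(cohort):
    return build_profiles(cohort)


@pytest.fixture(scope="session")
def outcomes(cohort):
    return build_outcomes(cohort)


@pytest.fixture(scope="session")
def levels(profiles):
    model = published_model()
    return assign_levels(profiles, score_profiles(profiles, model))
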