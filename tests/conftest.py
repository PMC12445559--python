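import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kneessm.shape import ShapePCA
from kneessm.synthetic import CohortParams, generate_cohort
from kneessm.template import make_template

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort used by several unit tests."""
    return generate_cohort(CohortParams(n_individuals=150, seed=42))


@pytest.fixture(scope="session")
def fitted_model(small_cohort):
    return ShapePCA([i.knee_landmarks for i in small_cohort.individuals]).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
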