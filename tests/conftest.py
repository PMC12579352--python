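import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from careernpv import (
    EconomicParams,
    GeneratorConfig,
    generate_compensation_table,
    generate_worked_fixture,
    make_career_plan,
)


@pytest.fixture(scope="session")
def worked_schedule():
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def alpha(worked_schedule):
    return worked_schedule["alpha"]


@pytest.fixture(scope="session")
def beta(worked_schedule):
    return worked_schedule["beta"]


@pytest.fixture
def std_plan(alpha):
    return make_career_plan("standard", alpha.career_years)


@pytest.fixture
def default_params():
    return EconomicParams()


@pytest.fixture(scope="session")
def synthetic_schedule():
    """Default-structure 29-specialty synthetic schedule, fixed seed."""
    return generate_compensation_table(GeneratorConfig(seed=20250101))
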