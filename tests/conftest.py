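import pytest
from hypothesis import settings

from ahc_cua.conditions import ModelContext

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ahc_cua.synthetic import paper_parameter_fixture


@pytest.fixture(scope="session")
def fixture_pset():
    return paper_parameter_fixture()


@pytest.fixture(scope="session")
def ctx(fixture_pset):
    return ModelContext.default(fixture_pset.metadata)


@pytest.fixture(scope="session")
def base_pm(fixture_pset):
    return fixture_pset.base_points()
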