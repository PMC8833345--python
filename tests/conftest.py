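import pytest

from snakeonc import outcome_model as om
from snakeonc.fixtures import builtin_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    return builtin_fixture("table1_census_cases")


@pytest.fixture(scope="session")
def fixture_design(fixture_bundle):
    return om.build_design(fixture_bundle.cases, seed=17)
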