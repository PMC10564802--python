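import pytest

from proteoharm.fixtures import (
    FixtureSpec,
    generate_annotation,
    generate_network_fixture,
    generate_study_tables,
    generate_use_case_fixture,
)


@pytest.fixture(scope="session")
def use_case():
    return generate_use_case_fixture()


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def annotation(default_spec):
    return generate_annotation(default_spec)


@pytest.fixture(scope="session")
def random_provider(annotation):
    return annotation[0]


@pytest.fixture(scope="session")
def manifest(annotation):
    return annotation[1]


@pytest.fixture(scope="session")
def random_studies(default_spec, random_provider):
    return generate_study_tables(default_spec, random_provider)


@pytest.fixture(scope="session")
def network_fixture(default_spec):
    return generate_network_fixture(default_spec)
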