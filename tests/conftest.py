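import pytest

from endochem import (
    builtin_models,
    load_fixture_profiles,
    load_fixture_survey,
    marker_registry,
    run_pipeline,
)


@pytest.fixture(scope="session")
def models():
    return builtin_models()


@pytest.fixture(scope="session")
def registry(models):
    return marker_registry(models)


@pytest.fixture(scope="session")
def field_profiles(models, registry):
    return load_fixture_profiles(registry)


@pytest.fixture(scope="session")
def field_profiles_by_id(field_profiles):
    return {p.strain_id: p for p in field_profiles}


@pytest.fixture(scope="session")
def field_results(field_profiles, models):
    return run_pipeline(field_profiles, models)


@pytest.fixture(scope="session")
def survey_records():
    return load_fixture_survey()
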