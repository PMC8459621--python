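import pytest

from cageload import GeneratorParams, default_composition, generate_cages, study_mean_cage


@pytest.fixture(scope="session")
def composition():
    return default_composition()


@pytest.fixture()
def mean_cage():
    """The deterministic study-mean cage record."""
    record, _ = study_mean_cage()
    return record


@pytest.fixture(scope="session")
def cohort():
    """A default 20-cage synthetic cohort plus its ground truth."""
    return generate_cages(GeneratorParams(seed=42))
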