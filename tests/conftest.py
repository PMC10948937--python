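import pytest

from dmrflow import pipeline
from dmrflow.synthetic_data import StudyConfig, generate_study

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """The default synthetic study at a fixed seed, shared session-wide."""
    return generate_study(StudyConfig(), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def results(study):
    """Full pipeline results over the shared study."""
    return pipeline.run_all(study)
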