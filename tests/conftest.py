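import pytest
from hypothesis import settings

from sscpgx import generate_cohort, margins_cohort, study_like_config

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_cohort():
    """A seeded study-like cohort (n=102, four variants, one LD pair)."""
    cohort, truth = generate_cohort(study_like_config(seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def margin_cohort():
    """Deterministic cohort reproducing the published demographic margins."""
    return margins_cohort()
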