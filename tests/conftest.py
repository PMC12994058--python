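import numpy as np
import pytest

from fspheno.scoring import score_cohort
from fspheno.synthetic import CohortConfig, default_archetypes, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Behavioral table at the study's group sizes (16/11/13/7), seed 0."""
    return generate_cohort(CohortConfig(default_archetypes(), seed=0))


@pytest.fixture(scope="session")
def large_cohort():
    """n=50 per archetype, used for pipeline-level recovery checks."""
    return generate_cohort(CohortConfig(default_archetypes(50), seed=7))


@pytest.fixture(scope="session")
def scored_large_cohort(large_cohort):
    scorecard, thresholds = score_cohort(large_cohort)
    return large_cohort, scorecard, thresholds


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
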