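import pytest
from hypothesis import settings

from edmargin import (
    PeriodSummary,
    generate_cohort,
    process_visits,
    study_like_config,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

# Published study aggregates (Table-1-style inputs to the model).
STUDY_PRE = PeriodSummary(n_visits=81_464, total_revenue=138_309_296.0, median_ed_los=311.0)
STUDY_POST = PeriodSummary(n_visits=89_259, total_revenue=153_747_123.0, median_ed_los=292.0)


@pytest.fixture(scope="session")
def study_pre() -> PeriodSummary:
    return STUDY_PRE


@pytest.fixture(scope="session")
def study_post() -> PeriodSummary:
    return STUDY_POST


@pytest.fixture(scope="session")
def study_like_cohort():
    """A moderately sized seeded draw from the study-like config.

    60k pre / 30k post keeps Monte-Carlo error on per-visit means near
    the 1% level while the whole suite stays fast.
    """
    config = study_like_config(seed=7, n_visits_pre=60_000, n_visits_post=30_000)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def processed_study_like(study_like_cohort):
    _, visits = study_like_cohort
    return process_visits(visits)
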