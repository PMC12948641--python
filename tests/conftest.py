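import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from airwayscore import (
    ContingencyTable2x2,
    reconstruct_cohort,
    study_score_distribution,
)


@pytest.fixture(scope="session")
def study_cohort():
    """The 200-patient cohort reconstructed from the printed margins."""
    return reconstruct_cohort(seed=1)


@pytest.fixture(scope="session")
def study_distribution():
    """Per-group score histogram inverted from the published cutoff sweep."""
    return study_score_distribution()


@pytest.fixture(scope="session")
def composite_table():
    """Published composite-score 2x2 against the MMC reference."""
    return ContingencyTable2x2(65, 34, 17, 84)
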