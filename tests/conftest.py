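from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import seatkit as sk

settings.register_profile(
    "seatkit",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("seatkit")


@pytest.fixture(scope="session")
def concept_day() -> dict:
    """The reconstructed concept-diagram day (30-min setting)."""
    return sk.build_concept_day_fixture()


@pytest.fixture(scope="session")
def cohort12() -> sk.Cohort:
    """Default 12-patient, 14-day synthetic cohort."""
    return sk.generate_cohort(sk.SyntheticConfig(n_patients=12, seed=1))
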