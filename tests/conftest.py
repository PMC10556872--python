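import datetime as dt

import pytest

from fifthcase.classification import CohortOvertimeProfile, split_successful
from fifthcase.schedule_io import ClockTime, day_from_times, parse_clock
from fifthcase.synthetic_data import GeneratorConfig, generate_cohort


def make_day(times, day_id="D1", date=dt.date(2015, 3, 2)):
    """Build a 4-case day from HH:MM[:SS] strings or second counts."""
    clocks = [parse_clock(t) if isinstance(t, str) else ClockTime(t) for t in times]
    return day_from_times(day_id, date, clocks)


@pytest.fixture
def linear_day():
    """An exactly linear day: 2-hour spacing from an 08:00 first case."""
    return make_day(["08:00", "10:00", "12:00", "14:00"])


@pytest.fixture(scope="session")
def study_profile():
    """Cohort profile built from the published aggregate counts."""
    return CohortOvertimeProfile.from_totals(
        n_days=761,
        n_successful=301,
        total_ochs_hours=465.375,
        total_spare_hours=97 + 49 / 60,
    )


@pytest.fixture(scope="session")
def synthetic_cohort():
    """One default-config 761-day cohort, shared across tests."""
    return generate_cohort(GeneratorConfig(), seed=123)


@pytest.fixture(scope="session")
def synthetic_successful(synthetic_cohort):
    succ, _ = split_successful(synthetic_cohort)
    return succ
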