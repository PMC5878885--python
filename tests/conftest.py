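import numpy as np
import pytest

from levelopt import (
    Cohort,
    ComplaintHierarchy,
    PatientRecord,
    SyntheticConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def abdominal_hierarchy() -> ComplaintHierarchy:
    """Two categories: abdominal pain (2 specific complaints) and headache (1)."""
    return ComplaintHierarchy.from_pairs([
        ("abdominal cramping", "abdominal pain"),
        ("abdominal mass", "abdominal pain"),
        ("tension headache", "headache"),
    ])


def make_record(complaint: str, outcome: int, **overrides) -> PatientRecord:
    fields = dict(
        age_band="40-49",
        gender="female",
        arrival_mode="walk_in",
        temperature_cat="96.1-99.2",
        pulse_cat="59-105",
        resp_rate_cat="14-19",
        bp_cat="106-176",
        o2sat_cat=">94",
        complaint=complaint,
        outcome=outcome,
    )
    fields.update(overrides)
    return PatientRecord(**fields)


@pytest.fixture(scope="session")
def abdominal_cohort(abdominal_hierarchy) -> Cohort:
    records = [
        make_record("abdominal cramping", 1),
        make_record("abdominal cramping", 0, gender="male"),
        make_record("abdominal mass", 0),
        make_record("abdominal mass", 1, age_band="70-79"),
        make_record("tension headache", 0),
        make_record("tension headache", 0, arrival_mode="ambulance"),
    ]
    return Cohort.from_records(records, abdominal_hierarchy)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-visit synthetic cohort with 4 informative complaints."""
    config = SyntheticConfig(
        n_patients=4000,
        n_categories=3,
        complaints_per_category=(3, 4),
        informative_complaint_count=4,
        specific_effect=1.0,
        target_prevalence=0.05,
        seed=1,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
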