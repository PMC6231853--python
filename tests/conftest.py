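import numpy as np
import pytest

from siteless.fixtures import records_from_marginals
from siteless.records import Demographics, ParticipantRecord, WeeklyResponse


def make_record(pid="p0001", group="A", last_active=1, preference="missing",
                medications=None, sex="female", age=48.0, ethnicity="white",
                bmi=29.5, education="college", smoking="never",
                disease_duration="2-5", joint_maps=(), rom_sessions=()):
    """Minimal valid participant record with overridable fields."""
    return ParticipantRecord(
        id=pid, group=group,
        demographics=Demographics(sex=sex, age=age, ethnicity=ethnicity,
                                  bmi=bmi, education=education, smoking=smoking,
                                  disease_duration=disease_duration),
        medications=medications, preference=preference,
        weekly=[WeeklyResponse(week=w) for w in range(1, last_active + 1)],
        joint_maps=list(joint_maps), rom_sessions=list(rom_sessions),
        last_active_week=last_active,
    )


@pytest.fixture(scope="session")
def study_marginal_records():
    """399 enrolled records reconstructed from the feasibility-study
    marginal counts: arms 197/202, preference 292/12/55/40, 45 retained
    at week 12 (26 vs 19 by arm), 162 retained at week 2, 322 female."""
    return records_from_marginals(
        group_sizes={"A": 197, "B": 202},
        preference_counts={"app": 292, "clinic": 12, "both": 55, "none": 40},
        week12_retained={"A": 26, "B": 19},
        week2_retained_total=162,
        n_female=322,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
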