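import numpy as np
import pytest

from nutrilcm.cohort import (
    CohortSpec,
    attach_survival,
    cohort_to_frame,
    generate_mechanistic_cohort,
)
from nutrilcm.criteria import PatientRecord, Sex, apply_all


def make_record(**kw) -> PatientRecord:
    """A baseline well-nourished record; override fields per test."""
    base = dict(
        id="T1",
        age=60.0,
        sex=Sex.MALE,
        bmi=24.0,
        wl_3mo_pct=0.0,
        wl_6mo_pct=0.0,
        wl_beyond_6mo_pct=0.0,
        wl_any_time_pct=0.0,
        ffmi=19.0,
        muscle_reduced_anthro=False,
        pgsga_score=0,
        nrs_positive=True,
        reduced_intake=False,
        has_cancer=True,
    )
    base.update(kw)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Mechanistic cohort with survival, n=800, fixed seed."""
    spec = CohortSpec(n_patients=800, seed=17)
    cohort = attach_survival(generate_mechanistic_cohort(spec), spec)
    return cohort


@pytest.fixture(scope="session")
def small_cohort_frame(small_cohort):
    return cohort_to_frame(small_cohort)


@pytest.fixture(scope="session")
def small_diagnoses(small_cohort):
    return apply_all(small_cohort.records)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
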