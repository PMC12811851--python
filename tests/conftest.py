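"""Shared fixtures, record factories and hypothesis strategies."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from alriscore.cohorts import STUDY_COHORTS, apply_cohort_filter
from alriscore.records import (
    SIGN_FLAGS,
    AdmissionRecord,
    ConsciousLevel,
    Outcome,
    Sex,
    make_signs,
)
from alriscore.scoring import load_score_definitions, required_fields_for
from alriscore.synthetic import generate_flowchart_fixture

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def make_record(**overrides) -> AdmissionRecord:
    """A complete, unremarkable admission; override any field."""
    base = dict(
        admission_id="T0001",
        age_months=8,
        sex=Sex.FEMALE,
        admission_date=date(2018, 6, 1),
        outcome=Outcome.DISCHARGED,
        resp_rate=35.0,
        spo2_percent=97,
        conscious_level=ConsciousLevel.NORMAL,
        muac_cm=13.5,
        waz=-0.5,
        wlz=-0.3,
        signs=make_signs(),
        alri_discharge_dx=True,
        severe_alri_presentation=True,
    )
    base.update(overrides)
    return AdmissionRecord(**base)


@st.composite
def admission_records(draw, allow_missing: bool = True, min_age: int = 1):
    """Random but valid admission records, optionally with missing fields.

    Scores and WHO breathing cutoffs are defined from 2 months; pass
    ``min_age=2`` when the records will be scored.
    """
    maybe = (
        (lambda s: st.one_of(st.none(), s)) if allow_missing else (lambda s: s)
    )
    age = draw(st.integers(min_value=min_age, max_value=59))
    signs = {}
    for flag in SIGN_FLAGS:
        tri = draw(st.sampled_from(["present", "absent"] + (["missing"] if allow_missing else [])))
        signs[flag] = None if tri == "missing" else tri == "present"
    return AdmissionRecord(
        admission_id=draw(st.uuids().map(str)),
        age_months=age,
        sex=draw(st.sampled_from(list(Sex))),
        admission_date=draw(
            st.dates(min_value=date(2015, 1, 1), max_value=date(2024, 12, 31))
        ),
        outcome=draw(st.sampled_from(list(Outcome))),
        resp_rate=draw(maybe(st.integers(min_value=10, max_value=120).map(float))),
        spo2_percent=draw(maybe(st.integers(min_value=50, max_value=100))),
        conscious_level=draw(maybe(st.sampled_from(list(ConsciousLevel)))),
        muac_cm=draw(
            maybe(st.floats(min_value=8.0, max_value=18.0, allow_nan=False).map(lambda x: round(x, 1)))
        ),
        waz=draw(
            maybe(st.floats(min_value=-5.0, max_value=3.0, allow_nan=False).map(lambda x: round(x, 2)))
        ),
        wlz=draw(
            maybe(st.floats(min_value=-5.0, max_value=3.0, allow_nan=False).map(lambda x: round(x, 2)))
        ),
        signs=signs,
        alri_discharge_dx=draw(st.booleans()),
        severe_alri_presentation=True,
    )


@pytest.fixture(scope="session")
def registry():
    return load_score_definitions()


@pytest.fixture(scope="session")
def flowchart():
    return generate_flowchart_fixture(seed=1)


@pytest.fixture(scope="session")
def cohort_a(flowchart, registry):
    """(included records, exclusion tally) for the main analysis cohort."""
    return apply_cohort_filter(
        flowchart, STUDY_COHORTS["A"], required_fields_for(registry)
    )
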