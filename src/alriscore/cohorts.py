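"""Study-cohort construction with flow-chart style exclusion accounting.

The main analysis population (cohort A) is children aged 2-24 months with a
primary or secondary discharge diagnosis of ALRI, an outcome of death or
discharge, and complete data for every score component (complete-case
analysis). Sensitivity cohorts relax one criterion each:

====  =========================================================
A     ages 2-24 months, ALRI diagnosis, complete case
B     ages 2-24 months, no diagnosis requirement
C     ages 2-59 months, ALRI diagnosis
D     as A but records with missing components retained
E     as A, excluding admissions in the first pandemic year
      (13 Mar 2020 - 13 Mar 2021, both ends inclusive)
F     as A, only admissions strictly before 13 Mar 2020
====  =========================================================

Exclusion reasons are applied in the fixed order
age -> diagnosis -> missing data -> outcome -> date, and each record is
counted under the first reason it triggers, so tallies are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

from .records import AdmissionRecord, Outcome, field_is_missing

__all__ = [
    "PANDEMIC_START",
    "CohortSpec",
    "ExclusionTally",
    "STUDY_COHORTS",
    "apply_cohort_filter",
]

#: Date of the first detected COVID-19 case in Kenya.
PANDEMIC_START = date(2020, 3, 13)
_PANDEMIC_YEAR_END = date(2021, 3, 13)

#: Outcomes retained for analysis; others ("absconded", "transferred") are excluded.
_ANALYSIS_OUTCOMES = frozenset({Outcome.DIED, Outcome.DISCHARGED})


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion rules for one study cohort."""

    cohort_id: str
    age_range_months: tuple[int, int]  # inclusive on both ends
    require_alri_dx: bool = True
    allow_missing: bool = False
    #: closed interval of admission dates to exclude, or None
    exclude_date_interval: tuple[date, date] | None = None
    #: keep only admissions strictly before this date, or None
    admitted_before: date | None = None

    def date_excluded(self, d: date) -> bool:
        if self.exclude_date_interval is not None:
            lo, hi = self.exclude_date_interval
            if lo <= d <= hi:
                return True
        if self.admitted_before is not None and d >= self.admitted_before:
            return True
        return False


STUDY_COHORTS: dict[str, CohortSpec] = {
    "A": CohortSpec("A", (2, 24)),
    "B": CohortSpec("B", (2, 24), require_alri_dx=False),
    "C": CohortSpec("C", (2, 59)),
    "D": CohortSpec("D", (2, 24), allow_missing=True),
    "E": CohortSpec(
        "E", (2, 24), exclude_date_interval=(PANDEMIC_START, _PANDEMIC_YEAR_END)
    ),
    "F": CohortSpec("F", (2, 24), admitted_before=PANDEMIC_START),
}


@dataclass
class ExclusionTally:
    """Counts of records by first triggering exclusion reason."""

    age_out_of_range: int = 0
    no_alri_dx: int = 0
    missing_data: int = 0
    other_outcome: int = 0
    date_excluded: int = 0
    included: int = 0

    REASONS = (
        "age_out_of_range",
        "no_alri_dx",
        "missing_data",
        "other_outcome",
        "date_excluded",
        "included",
    )

    def total(self) -> int:
        return sum(getattr(self, r) for r in self.REASONS)

    def as_dict(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in self.REASONS}


def apply_cohort_filter(
    records: Iterable[AdmissionRecord],
    spec: CohortSpec,
    required_fields: Sequence[str] = (),
) -> tuple[list[AdmissionRecord], ExclusionTally]:
    """Apply one cohort's inclusion rules, counting exclusions by reason.

    *required_fields* is the union of record fields needed by the scores under
    evaluation (complete-case criterion); it is ignored when the spec allows
    missing data (cohort D semantics). The tally always satisfies
    ``tally.total() == len(records)``.
    """
    lo, hi = spec.age_range_months
    tally = ExclusionTally()
    included: list[AdmissionRecord] = []
    for r in records:
        if not lo <= r.age_months <= hi:
            tally.age_out_of_range += 1
        elif spec.require_alri_dx and not r.alri_discharge_dx:
            tally.no_alri_dx += 1
        elif not spec.allow_missing and any(
            field_is_missing(r, f) for f in required_fields
        ):
            tally.missing_data += 1
        elif r.outcome not in _ANALYSIS_OUTCOMES:
            tally.other_outcome += 1
        elif spec.date_excluded(r.admission_date):
            tally.date_excluded += 1
        else:
            tally.included += 1
            included.append(r)
    return included, tally
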