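"""Grade-year cohort construction from enrollment records.

A person joins a cohort when enrolled in its CohortSpec's grade and school year,
carrying no exclusion flag, with attained age on Sept 1 inside the grade's
age window, and (if censored) censored only after the observation end.
Rejections are tallied under the first matching reason in the fixed order
flag > age > censoring > repeat enrollment, so tallies are deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from . import study
from .dates import (
    attained_age,
    entry_month,
    month_end,
    month_index,
    parse_month,
    parse_school_year,
    reference_month,
    month_label,
    school_year_entry,
)
from .errors import ConfigError
from .registry_model import EnrollmentRecord, FLAG_ORDER, PersonRecord


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """One grade-year cohort definition.

    ``program_grade`` groups cohorts belonging to the same delivery program
    (the Grade 5 2017-2018 baseline anchors the Grade 6 program).
    ``reference_month`` (July of the grade-year end) is month 0 of the
    follow-up axis; Grade 1 coverage tracking starts at September of the
    grade year (``coverage_start_month``), i.e. month −10.
    """

    grade: int
    school_year: str
    role: str  # "prepandemic" | "pandemic"
    age_window: tuple[int, int]
    reference_month: str
    coverage_start_month: str
    observation_end: str
    program_grade: int

    def __post_init__(self) -> None:
        parse_school_year(self.school_year)
        if self.role not in ("prepandemic", "pandemic"):
            raise ConfigError(f"unknown cohort role {self.role!r}")
        lo, hi = self.age_window
        if lo > hi:
            raise ConfigError(f"age window min {lo} > max {hi}")
        ref = parse_month(self.reference_month)
        first, _ = parse_school_year(self.school_year)
        if not month_index(first, 9) <= ref <= month_index(first + 1, 8):
            raise ConfigError(
                f"reference month {self.reference_month} outside school year "
                f"{self.school_year} (or the month after it)"
            )

    @property
    def cohort_id(self) -> str:
        return f"G{self.grade}_{self.school_year}"


@dataclasses.dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    members: tuple[str, ...]  # sorted person_ids
    exclusion_tally: Mapping[str, int]

    @property
    def cohort_id(self) -> str:
        return self.spec.cohort_id

    @property
    def size(self) -> int:
        return len(self.members)


@dataclasses.dataclass(frozen=True)
class CohortMemberRow:
    cohort_id: str
    person_id: str

    KEY = ("cohort_id", "person_id")


@dataclasses.dataclass(frozen=True)
class ExclusionRow:
    cohort_id: str
    reason: str
    count: int

    KEY = ("cohort_id", "reason")


def build_cohorts(
    persons: Sequence[PersonRecord],
    enrollments: Sequence[EnrollmentRecord],
    specs: Sequence[CohortSpec],
) -> list[Cohort]:
    """Materialize cohorts, applying eligibility rules in fixed precedence.

    Persons enrolled in the same grade in two qualifying years (repeaters)
    are kept in their first qualifying cohort only, so cohorts of one grade
    are disjoint.
    """
    seen_keys = set()
    for spec in specs:
        key = (spec.grade, spec.school_year)
        if key in seen_keys:
            raise ConfigError(f"overlapping cohort specs for grade {spec.grade}, {spec.school_year}")
        seen_keys.add(key)

    by_id = {p.person_id: p for p in persons}
    by_cohort: dict[tuple[int, str], list[EnrollmentRecord]] = {}
    for e in enrollments:
        by_cohort.setdefault((e.grade, e.school_year), []).append(e)

    cohorts: list[Cohort] = []
    assigned_by_grade: dict[int, set[str]] = {}
    for spec in sorted(specs, key=lambda s: (s.grade, s.school_year)):
        rows = sorted(
            by_cohort.get((spec.grade, spec.school_year), []),
            key=lambda e: e.person_id,
        )
        sept1 = school_year_entry(spec.school_year)
        obs_end_day = month_end(parse_month(spec.observation_end))
        lo, hi = spec.age_window
        members: list[str] = []
        tally: dict[str, int] = {}
        taken = assigned_by_grade.setdefault(spec.grade, set())
        for e in rows:
            person = by_id[e.person_id]
            reason = None
            if e.exclusion_flags:
                reason = next(f for f in FLAG_ORDER if f in e.exclusion_flags)
            elif not lo <= attained_age(person.birth_date, sept1) <= hi:
                reason = "age"
            elif person.censor_date is not None and person.censor_date <= obs_end_day:
                reason = "censoring"
            elif e.person_id in taken:
                reason = "repeat_enrollment"
            if reason is None:
                members.append(e.person_id)
                taken.add(e.person_id)
            else:
                tally[reason] = tally.get(reason, 0) + 1
        cohorts.append(Cohort(spec=spec, members=tuple(members), exclusion_tally=tally))
    return cohorts


def default_specs(
    pandemic_years: Sequence[str] = study.PANDEMIC_YEARS,
    prepandemic: Mapping[int, tuple[int, str]] = study.PREPANDEMIC,
    observation_end: str = study.OBSERVATION_END,
    age_windows: Mapping[int, tuple[int, int]] = study.AGE_WINDOWS,
) -> list[CohortSpec]:
    """The default 15-cohort design: 5 annual cohorts per program grade."""
    specs: list[CohortSpec] = []
    for program_grade in study.PROGRAM_GRADES:
        pre_grade, pre_year = prepandemic[program_grade]
        plan = [(pre_grade, pre_year, "prepandemic")] + [
            (program_grade, year, "pandemic") for year in pandemic_years
        ]
        for grade, year, role in plan:
            ref = month_label(reference_month(year))
            start = month_label(entry_month(year)) if program_grade == 1 else ref
            specs.append(
                CohortSpec(
                    grade=grade,
                    school_year=year,
                    role=role,
                    age_window=age_windows[grade],
                    reference_month=ref,
                    coverage_start_month=start,
                    observation_end=observation_end,
                    program_grade=program_grade,
                )
            )
    return specs
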