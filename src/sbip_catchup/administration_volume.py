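"""Dose delivery volume: routine vs catch-up classification and period counts.

A dose delivered to a cohort member is *routine* when dated inside the
scheduled grade year (Sept 1 – June 30) and *catch-up* when dated after
June 30 of the grade year. Doses predating the grade year (e.g. preschool
doses of a Grade 1 series) are left unclassified and logged: they count
toward coverage but not toward program delivery volume. Counts are dose
counts, not person counts (optionally restricted to first doses).

Monthly counts collapse into "school year" (September–June) and "summer"
(July–August) periods; annual catch-up uptake pools catch-up doses across
all pandemic cohorts of a grade over July 1 – June 30 windows.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

from .cohort_builder import Cohort, CohortSpec
from .dates import (
    month_index,
    month_label,
    month_of,
    parse_month,
    school_year_classes_end,
    school_year_entry,
    school_year_label,
)
from .errors import ConfigError
from .registry_model import DoseRecord, SeriesSpec

log = logging.getLogger(__name__)

ROUTINE = "routine"
CATCHUP = "catchup"


@dataclasses.dataclass(frozen=True)
class PeriodVolume:
    cohort_id: str
    antigen_group: str
    period_type: str  # "school_year" | "summer"
    period_span: str  # "2021-2022" for school years, "2022" for summers
    routine_count: int
    catchup_count: int

    KEY = ("cohort_id", "antigen_group", "period_span", "period_type")


@dataclasses.dataclass(frozen=True)
class AnnualUptake:
    """Catch-up doses per July–June window, pooled over a grade's pandemic cohorts."""

    per_window: Mapping[str, int]  # window label "YYYY-YYYY" -> catch-up doses
    max_uptake: int
    mean_uptake: float


def classify_dose(dose: DoseRecord, spec: CohortSpec) -> str | None:
    """Classify a cohort member's dose as routine, catch-up, or None.

    None (unclassified) marks doses predating the grade year; the caller is
    expected to log and skip them.
    """
    start = school_year_entry(spec.school_year)
    classes_end = school_year_classes_end(spec.school_year)
    d = dose.administration_date
    if start <= d <= classes_end:
        return ROUTINE
    if d > classes_end:
        return CATCHUP
    return None


def period_of(month_idx: int) -> tuple[str, str]:
    """Map an absolute month index to its (period_type, period_span)."""
    year, month = month_idx // 12, month_idx % 12 + 1
    if month in (7, 8):
        return "summer", str(year)
    start_year = year if month >= 9 else year - 1
    return "school_year", school_year_label(start_year)


def periods_in_range(start_month: str, end_month: str) -> list[tuple[str, str]]:
    """Ordered distinct periods partitioning [start_month, end_month]."""
    out: list[tuple[str, str]] = []
    for idx in range(parse_month(start_month), parse_month(end_month) + 1):
        p = period_of(idx)
        if not out or out[-1] != p:
            out.append(p)
    return out


def period_volumes(
    cohort: Cohort,
    doses: Sequence[DoseRecord],
    series: SeriesSpec,
    study_range: tuple[str, str],
    count_mode: str = "all_doses",
) -> list[PeriodVolume]:
    """Routine/catch-up dose counts per period for one cohort and series.

    Every classified dose inside ``study_range`` is counted exactly once.
    ``count_mode="first_dose_only"`` counts series initiations instead of all
    qualifying doses.
    """
    if count_mode not in ("all_doses", "first_dose_only"):
        raise ConfigError(f"unknown count_mode {count_mode!r}")
    members = set(cohort.members)
    lo, hi = parse_month(study_range[0]), parse_month(study_range[1])
    counts: dict[tuple[str, str], dict[str, int]] = {
        p: {ROUTINE: 0, CATCHUP: 0} for p in periods_in_range(*study_range)
    }

    relevant = sorted(
        (d for d in doses if d.person_id in members and d.antigen_group == series.antigen_group),
        key=lambda d: (d.person_id, d.administration_date),
    )
    seen_first: set[str] = set()
    unclassified = 0
    for d in relevant:
        is_first = d.person_id not in seen_first
        seen_first.add(d.person_id)
        if count_mode == "first_dose_only" and not is_first:
            continue
        cls = classify_dose(d, cohort.spec)
        if cls is None:
            unclassified += 1
            continue
        idx = month_of(d.administration_date)
        if not lo <= idx <= hi:
            continue
        counts[period_of(idx)][cls] += 1
    if unclassified:
        log.info(
            "cohort %s/%s: %d dose(s) predate the grade year; excluded from volume",
            cohort.cohort_id, series.antigen_group, unclassified,
        )

    return [
        PeriodVolume(
            cohort_id=cohort.cohort_id,
            antigen_group=series.antigen_group,
            period_type=ptype,
            period_span=span,
            routine_count=c[ROUTINE],
            catchup_count=c[CATCHUP],
        )
        for (ptype, span), c in counts.items()
    ]


def _window_of(volume: PeriodVolume) -> str:
    """July–June catch-up window containing a period.

    Summer ``"2023"`` and school year ``"2023-2024"`` both fall in window
    ``"2023-2024"`` (July 2023 – June 2024).
    """
    if volume.period_type == "summer":
        year = int(volume.period_span)
    else:
        year = int(volume.period_span.split("-")[0])
    return school_year_label(year)


def annual_catchup_uptake(
    volumes: Sequence[PeriodVolume],
    cohorts: Sequence[Cohort],
    grade: int,
    series: SeriesSpec,
    study_range: tuple[str, str],
) -> AnnualUptake:
    """Annual (July 1 – June 30) catch-up dose totals for one grade and series.

    Pools catch-up doses over all pandemic cohorts of the program grade.
    Windows run from July of the earliest pandemic grade-year end through the
    last complete July–June window inside ``study_range``; incomplete trailing
    windows are dropped.
    """
    pandemic = [
        c for c in cohorts if c.spec.program_grade == grade and c.spec.role == "pandemic"
    ]
    if not pandemic:
        raise ConfigError(f"no pandemic cohorts for grade {grade}")
    pandemic_ids = {c.cohort_id for c in pandemic}
    first_july_year = min(parse_month(c.spec.reference_month) for c in pandemic) // 12

    end_idx = parse_month(study_range[1])
    windows: list[str] = []
    year = first_july_year
    while month_index(year + 1, 6) <= end_idx:  # window complete through June
        windows.append(school_year_label(year))
        year += 1
    if not windows:
        raise ConfigError(
            f"no complete July–June window between {month_label(month_index(first_july_year, 7))} "
            f"and {study_range[1]}"
        )

    per_window = {w: 0 for w in windows}
    for v in volumes:
        if v.cohort_id in pandemic_ids and v.antigen_group == series.antigen_group:
            w = _window_of(v)
            if w in per_window:
                per_window[w] += v.catchup_count
    totals = list(per_window.values())
    return AnnualUptake(
        per_window=per_window,
        max_uptake=max(totals),
        mean_uptake=sum(totals) / len(totals),
    )
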