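"""Cumulative immunization deficits and projected catch-up time.

For each grade and vaccine series, the *expected* number vaccinated is the
prepandemic cohort's maximum observed coverage applied to each pandemic
cohort's size (summed as reals, rounded half-up once); the *cumulative
deficit* is observed − expected (negative = shortfall). Dividing a shortfall
by the grade's observed annual catch-up uptake gives the projected years of
continued catch-up effort to clear it: the minimum estimate uses the maximum
annual uptake, the average estimate the mean annual uptake.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

from .administration_volume import AnnualUptake, PeriodVolume, annual_catchup_uptake
from .cohort_builder import Cohort
from .coverage_engine import CoveragePoint
from .errors import ConfigError
from .registry_model import SeriesSpec


@dataclasses.dataclass(frozen=True)
class DeficitReport:
    grade: int
    antigen_group: str
    expected_vaccinated: int
    observed_vaccinated: int
    cumulative_deficit: int
    max_annual_uptake: int
    avg_annual_uptake: float
    min_years_to_clear: float
    avg_years_to_clear: float

    KEY = ("grade", "antigen_group")


def expected_vaccinated(
    prepandemic_end_coverage: float, pandemic_cohort_sizes: Sequence[int]
) -> int:
    """Counterfactual vaccinated count: coverage × each cohort size, summed
    as reals and rounded half-up once at the end."""
    if not 0.0 <= prepandemic_end_coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    if any(n < 0 for n in pandemic_cohort_sizes):
        raise ValueError("cohort sizes must be >= 0")
    total = prepandemic_end_coverage * sum(pandemic_cohort_sizes)
    return math.floor(total + 0.5)


def cumulative_deficit(expected: int, observed: int) -> int:
    """Observed − expected vaccinated (negative when coverage fell short)."""
    if expected < 0 or observed < 0:
        raise ValueError("counts must be >= 0")
    return observed - expected


def time_to_clear(deficit: int, annual_uptake: float) -> float:
    """Years of catch-up effort at ``annual_uptake`` doses/year to clear a
    shortfall; 0 when there is no shortfall."""
    if deficit >= 0:
        return 0.0
    if annual_uptake <= 0:
        raise ConfigError("deficit cannot be cleared: annual catch-up uptake is <= 0")
    return abs(deficit) / annual_uptake


def round_years(years: float) -> float:
    """Report rounding: 2 decimals below one year, 1 decimal otherwise."""
    return round(years, 2) if years < 1.0 else round(years, 1)


def deficit_table(
    coverage: Sequence[CoveragePoint],
    volumes: Sequence[PeriodVolume],
    cohorts: Sequence[Cohort],
    series_registry: Mapping[int, Sequence[SeriesSpec]],
    study_range: tuple[str, str],
) -> list[DeficitReport]:
    """One deficit row per (program grade, series).

    Prepandemic coverage is taken at its maximum observed month (for a
    cumulative curve this is the end of study); observed counts are the
    pandemic cohorts' covered members at observation end, at each cohort
    year's complete-series threshold.
    """
    by_key: dict[tuple[str, str, int], list[CoveragePoint]] = {}
    for p in coverage:
        by_key.setdefault((p.cohort_id, p.antigen_group, p.dose_threshold), []).append(p)

    reports: list[DeficitReport] = []
    for grade in sorted(series_registry):
        grade_cohorts = [c for c in cohorts if c.spec.program_grade == grade]
        pre = [c for c in grade_cohorts if c.spec.role == "prepandemic"]
        if len(pre) != 1:
            raise ConfigError(f"grade {grade}: expected exactly one prepandemic cohort, got {len(pre)}")
        pre_cohort = pre[0]
        pandemic = sorted(
            (c for c in grade_cohorts if c.spec.role == "pandemic"),
            key=lambda c: c.spec.school_year,
        )
        for series in series_registry[grade]:
            pre_threshold = series.required_doses(pre_cohort.spec.school_year)
            pre_points = by_key.get((pre_cohort.cohort_id, series.antigen_group, pre_threshold))
            if not pre_points:
                raise ConfigError(
                    f"missing prepandemic coverage for grade {grade}, {series.antigen_group}"
                )
            pre_max = max(p.proportion for p in pre_points)

            sizes, observed = [], 0
            for c in pandemic:
                threshold = series.required_doses(c.spec.school_year)
                points = by_key.get((c.cohort_id, series.antigen_group, threshold))
                if not points:
                    raise ConfigError(
                        f"missing coverage for cohort {c.cohort_id}, {series.antigen_group}"
                    )
                last = max(points, key=lambda p: p.calendar_month)
                sizes.append(last.n_total)
                observed += last.n_covered

            expected = expected_vaccinated(pre_max, sizes)
            deficit = cumulative_deficit(expected, observed)
            uptake: AnnualUptake = annual_catchup_uptake(
                volumes, cohorts, grade, series, study_range
            )
            reports.append(
                DeficitReport(
                    grade=grade,
                    antigen_group=series.antigen_group,
                    expected_vaccinated=expected,
                    observed_vaccinated=observed,
                    cumulative_deficit=deficit,
                    max_annual_uptake=uptake.max_uptake,
                    avg_annual_uptake=uptake.mean_uptake,
                    min_years_to_clear=round_years(time_to_clear(deficit, uptake.max_uptake)),
                    avg_years_to_clear=round_years(time_to_clear(deficit, uptake.mean_uptake)),
                )
            )
    return reports
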