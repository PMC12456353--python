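"""Synthetic immunization registry with analytic ground truth.

The generator draws linked person/enrollment/dose tables from a discrete-time
monthly vaccination hazard model:

* each cohort member is, independently, a **refuser** (probability *r*, never
  vaccinated), **complete at entry** (probability *prior*, holds the full
  series before Sept 1 of the grade year), or **active**;
* an active member attempts at most one pending dose per month: during a
  dose's scheduled months (offsets within the grade year) the success
  probability is the baseline hazard ``h_m``, multiplied by the disruption
  factor δ when the calendar month falls inside the disruption window; in
  months after the dose's scheduled window the catch-up hazard *c* applies;
* dose dates are uniform within their month; birth dates are uniform within
  the grade's age window.

Because the model is a per-person Markov chain over dose states, the exact
expected cumulative coverage curve is available in closed form by dynamic
programming over dose-state occupancy (:func:`analytic_coverage`), and each
simulated study carries this curve — plus the analytic end-of-study deficit
against a δ=1 reference — as its :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import NamedTuple, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from . import study
from .dates import (
    days_in_month,
    entry_month,
    month_label,
    month_start,
    parse_month,
    parse_school_year,
)
from .errors import ConfigError
from .registry_model import DoseRecord, EnrollmentRecord, PersonRecord


class SeriesSim(BaseModel):
    """Generative parameters for one vaccine series in one program grade."""

    antigen_group: str
    grade: int  # program grade this series belongs to
    required_doses: dict[str, int] = Field(default_factory=lambda: {"default": 1})
    entry_complete_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    #: doses delivered through the grade-year program; None = the full series.
    #: Grade 1 series set this to 1 (final dose only; earlier doses predate entry).
    pending_doses: Optional[int] = Field(default=None, ge=1)
    #: per pending dose, scheduled month-offset (0 = Sept) -> monthly hazard
    dose_hazards: list[dict[int, float]]
    catchup_hazard: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    refuser_fraction: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    product_codes: list[str] = Field(default_factory=lambda: ["GEN"])

    @field_validator("dose_hazards")
    @classmethod
    def _hazards_are_probabilities(cls, v: list[dict[int, float]]) -> list[dict[int, float]]:
        if not v:
            raise ValueError("dose_hazards must not be empty")
        for sched in v:
            if not sched:
                raise ValueError("each pending dose needs at least one scheduled month")
            for off, h in sched.items():
                if off < 0:
                    raise ValueError(f"negative month offset {off}")
                if not 0.0 <= h <= 1.0:
                    raise ValueError(f"hazard {h} at offset {off} outside [0, 1]")
        return v

    @field_validator("required_doses")
    @classmethod
    def _doses_positive(cls, v: dict[str, int]) -> dict[str, int]:
        for year, k in v.items():
            if k < 1:
                raise ValueError(f"required dose count for {year!r} must be >= 1")
        return v

    def doses_required(self, school_year: str) -> int:
        if school_year in self.required_doses:
            return self.required_doses[school_year]
        return self.required_doses["default"]

    def pending_for(self, school_year: str) -> int:
        k = self.doses_required(school_year)
        pending = k if self.pending_doses is None else min(self.pending_doses, k)
        if len(self.dose_hazards) < pending:
            raise ConfigError(
                f"{self.antigen_group}: {pending} pending doses but only "
                f"{len(self.dose_hazards)} hazard schedule(s)"
            )
        return pending


class CohortSim(BaseModel):
    grade: int
    school_year: str
    size: int = Field(ge=0)
    role: str = "pandemic"
    program_grade: Optional[int] = None  # defaults to grade

    @field_validator("school_year")
    @classmethod
    def _valid_year(cls, v: str) -> str:
        parse_school_year(v)
        return v

    @property
    def program(self) -> int:
        return self.program_grade if self.program_grade is not None else self.grade

    @property
    def cohort_id(self) -> str:
        return f"G{self.grade}_{self.school_year}"


class SimulationConfig(BaseModel):
    seed: int = Field(ge=0)
    cohorts: list[CohortSim]
    series: list[SeriesSim]
    refuser_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    disruption_window: tuple[str, str] = ("2020-03", "2021-06")
    disruption_multiplier: float = Field(default=1.0, ge=0.0, le=1.0)
    catchup_hazard: float = Field(default=0.0, ge=0.0, le=1.0)
    observation_end: str = study.OBSERVATION_END
    online_only_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    censor_fraction: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _window_ordered(self) -> "SimulationConfig":
        lo, hi = self.disruption_window
        if parse_month(lo) > parse_month(hi):
            raise ValueError(f"disruption window start {lo} after end {hi}")
        parse_month(self.observation_end)
        return self

    def series_for(self, program_grade: int) -> list[SeriesSim]:
        return [s for s in self.series if s.grade == program_grade]


@dataclasses.dataclass(frozen=True)
class GroundTruthPoint:
    cohort_id: str
    antigen_group: str
    calendar_month: str
    expected_coverage: float

    KEY = ("cohort_id", "antigen_group", "calendar_month")


@dataclasses.dataclass(frozen=True)
class GroundTruthDeficit:
    """Analytic end-of-study deficit of one cohort/series vs a δ=1 reference."""

    cohort_id: str
    antigen_group: str
    cohort_size: int
    expected_coverage_end: float
    reference_coverage_end: float  # same model with disruption switched off
    expected_deficit: float  # size × (expected − reference); ≤ 0 under disruption

    KEY = ("cohort_id", "antigen_group")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    points: tuple[GroundTruthPoint, ...]
    deficits: tuple[GroundTruthDeficit, ...]

    def curve(self, cohort_id: str, antigen_group: str) -> dict[str, float]:
        return {
            p.calendar_month: p.expected_coverage
            for p in self.points
            if p.cohort_id == cohort_id and p.antigen_group == antigen_group
        }

    def deficit(self, cohort_id: str, antigen_group: str) -> GroundTruthDeficit:
        for d in self.deficits:
            if d.cohort_id == cohort_id and d.antigen_group == antigen_group:
                return d
        raise KeyError((cohort_id, antigen_group))


class SimulationOutput(NamedTuple):
    persons: list[PersonRecord]
    enrollments: list[EnrollmentRecord]
    doses: list[DoseRecord]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Hazard machinery shared by the sampler and the analytic oracle


def _hazard_matrix(
    config: SimulationConfig,
    cohort: CohortSim,
    series: SeriesSim,
    pending: int,
    n_months: int,
    disruption_multiplier: float | None = None,
) -> np.ndarray:
    """Per (pending dose, month-since-entry) success probability."""
    delta = (
        config.disruption_multiplier
        if disruption_multiplier is None
        else disruption_multiplier
    )
    c = series.catchup_hazard if series.catchup_hazard is not None else config.catchup_hazard
    dw_lo = parse_month(config.disruption_window[0])
    dw_hi = parse_month(config.disruption_window[1])
    entry = entry_month(cohort.school_year)
    q = np.zeros((max(pending, 1), n_months))
    for j in range(pending):
        sched = series.dose_hazards[j]
        last_scheduled = max(sched)
        for t in range(n_months):
            cal = entry + t
            if t in sched:
                h = sched[t]
                if dw_lo <= cal <= dw_hi:
                    h *= delta
                q[j, t] = h
            elif t > last_scheduled:
                q[j, t] = c
    return q


def _completion_curve(q: np.ndarray, pending: int) -> np.ndarray:
    """P(all pending doses received by end of month t), for each t.

    Dynamic programming over dose-state occupancy; at most one dose per
    month, dose j+1 attemptable only from the month after dose j.
    """
    n_months = q.shape[1]
    if pending == 0:
        return np.ones(n_months)
    occ = np.zeros(pending + 1)
    occ[0] = 1.0
    out = np.empty(n_months)
    for t in range(n_months):
        move = occ[:pending] * q[:pending, t]
        occ[:pending] -= move
        occ[1:] += move
        out[t] = occ[pending]
    return out


def _resolve(config: SimulationConfig, cohort, series) -> tuple[CohortSim, SeriesSim]:
    if isinstance(cohort, str):
        matches = [c for c in config.cohorts if c.cohort_id == cohort]
        if not matches:
            raise ConfigError(f"unknown cohort {cohort!r}")
        cohort = matches[0]
    if isinstance(series, str):
        matches = [s for s in config.series_for(cohort.program) if s.antigen_group == series]
        if not matches:
            raise ConfigError(f"no series {series!r} for program grade {cohort.program}")
        series = matches[0]
    return cohort, series


def analytic_coverage(
    config: SimulationConfig,
    cohort: CohortSim | str,
    series: SeriesSim | str,
    month: str,
    disruption_multiplier: float | None = None,
) -> float:
    """Exact expected complete-series coverage of a cohort at a calendar month.

    ``C(t) = prior + (1 − prior − r) · P(active member completed by t)``, the
    completion probability coming from the dose-state dynamic program.
    Months before the cohort's entry month return the entry-time coverage
    (``prior``).
    """
    cohort, series = _resolve(config, cohort, series)
    entry = entry_month(cohort.school_year)
    t = parse_month(month) - entry
    r = (
        series.refuser_fraction
        if series.refuser_fraction is not None
        else config.refuser_fraction
    )
    prior = series.entry_complete_fraction
    if t < 0:
        return prior
    pending = series.pending_for(cohort.school_year)
    q = _hazard_matrix(config, cohort, series, pending, t + 1, disruption_multiplier)
    done = _completion_curve(q, pending)
    return prior + (1.0 - prior - r) * float(done[t])


def analytic_ground_truth(config: SimulationConfig) -> GroundTruth:
    points: list[GroundTruthPoint] = []
    deficits: list[GroundTruthDeficit] = []
    end = parse_month(config.observation_end)
    for cohort in config.cohorts:
        entry = entry_month(cohort.school_year)
        n_months = end - entry + 1
        for series in config.series_for(cohort.program):
            r = (
                series.refuser_fraction
                if series.refuser_fraction is not None
                else config.refuser_fraction
            )
            prior = series.entry_complete_fraction
            pending = series.pending_for(cohort.school_year)
            q = _hazard_matrix(config, cohort, series, pending, n_months)
            curve = prior + (1.0 - prior - r) * _completion_curve(q, pending)
            q_ref = _hazard_matrix(config, cohort, series, pending, n_months, 1.0)
            curve_ref = prior + (1.0 - prior - r) * _completion_curve(q_ref, pending)
            for t in range(n_months):
                points.append(
                    GroundTruthPoint(
                        cohort_id=cohort.cohort_id,
                        antigen_group=series.antigen_group,
                        calendar_month=month_label(entry + t),
                        expected_coverage=float(curve[t]),
                    )
                )
            deficits.append(
                GroundTruthDeficit(
                    cohort_id=cohort.cohort_id,
                    antigen_group=series.antigen_group,
                    cohort_size=cohort.size,
                    expected_coverage_end=float(curve[-1]),
                    reference_coverage_end=float(curve_ref[-1]),
                    expected_deficit=cohort.size * float(curve[-1] - curve_ref[-1]),
                )
            )
    return GroundTruth(points=tuple(points), deficits=tuple(deficits))


# ---------------------------------------------------------------------------
# Sampling


def _sample_preentry_dates(
    rng: np.random.Generator,
    birth_ordinals: np.ndarray,
    entry_ordinal: int,
    n_doses: int,
) -> np.ndarray:
    """(n, n_doses) strictly increasing dose-day ordinals before entry.

    Doses land uniformly between 6 weeks after birth and the day before
    entry; sorting plus a per-column offset guarantees distinct days.
    """
    n = len(birth_ordinals)
    lo = birth_ordinals + 42
    span = (entry_ordinal - 1) - lo + 1 - n_doses
    span = np.maximum(span, 1)
    raw = np.sort(rng.random((n, n_doses)), axis=1)
    days = np.floor(raw * span[:, None]).astype(np.int64)
    return lo[:, None] + days + np.arange(n_doses)[None, :]


def simulate(config: SimulationConfig) -> SimulationOutput:
    """Draw a full synthetic registry; reproducible byte-for-byte given seed."""
    rng = np.random.default_rng(config.seed)
    end = parse_month(config.observation_end)

    persons: list[PersonRecord] = []
    enrollments: list[EnrollmentRecord] = []
    doses: list[DoseRecord] = []

    for ci, cohort in enumerate(config.cohorts):
        n = cohort.size
        entry = entry_month(cohort.school_year)
        entry_day = month_start(entry)
        entry_ord = entry_day.toordinal()
        n_months = end - entry + 1
        if n_months <= 0:
            raise ConfigError(
                f"cohort {cohort.cohort_id} starts after observation end"
            )
        a_min, a_max = study.AGE_WINDOWS[cohort.grade]
        first_year, _ = parse_school_year(cohort.school_year)

        lo = dt.date(first_year - a_max - 1, 9, 1).toordinal() + 1
        hi = dt.date(first_year - a_min, 9, 1).toordinal()
        birth_ord = rng.integers(lo, hi + 1, size=n)
        sex = rng.integers(0, 2, size=n)
        n_schools = max(1, n // 400)
        school = rng.integers(0, n_schools, size=n)
        flagged = rng.random(n) < config.online_only_fraction
        censored = rng.random(n) < config.censor_fraction
        censor_day = rng.integers(entry_ord, month_start(end).toordinal() + 1, size=n)

        pids = [f"{cohort.cohort_id}-{i:06d}" for i in range(n)]
        for i in range(n):
            persons.append(
                PersonRecord(
                    person_id=pids[i],
                    birth_date=dt.date.fromordinal(int(birth_ord[i])),
                    censor_date=(
                        dt.date.fromordinal(int(censor_day[i])) if censored[i] else None
                    ),
                    sex="F" if sex[i] else "M",
                )
            )
            enrollments.append(
                EnrollmentRecord(
                    person_id=pids[i],
                    school_year=cohort.school_year,
                    grade=cohort.grade,
                    school_id=f"S{cohort.grade:02d}-{int(school[i]):03d}",
                    exclusion_flags=frozenset({"online_only"}) if flagged[i] else frozenset(),
                )
            )

        u_refuse = rng.random(n)  # person-level; shared across series
        for series in config.series_for(cohort.program):
            r = (
                series.refuser_fraction
                if series.refuser_fraction is not None
                else config.refuser_fraction
            )
            prior = series.entry_complete_fraction
            if prior + r > 1.0 + 1e-12:
                raise ConfigError(
                    f"{series.antigen_group}: refuser fraction {r} + entry-complete "
                    f"fraction {prior} exceeds 1"
                )
            k = series.doses_required(cohort.school_year)
            pending = series.pending_for(cohort.school_year)
            at_entry = k - pending

            refuser = u_refuse < r
            v = rng.random(n)
            complete = (~refuser) & (v < (prior / (1.0 - r) if r < 1.0 else 0.0))
            active = ~(refuser | complete)

            codes = series.product_codes

            def _emit(pid_idx: np.ndarray, day_matrix: np.ndarray) -> None:
                if day_matrix.size == 0:
                    return
                code_idx = rng.integers(0, len(codes), size=day_matrix.shape)
                for row, pi in enumerate(pid_idx):
                    pid = pids[int(pi)]
                    for col in range(day_matrix.shape[1]):
                        day = int(day_matrix[row, col])
                        if day < 0:
                            continue
                        doses.append(
                            DoseRecord(
                                person_id=pid,
                                antigen_group=series.antigen_group,
                                product_code=codes[int(code_idx[row, col])],
                                administration_date=dt.date.fromordinal(day),
                            )
                        )

            # complete-at-entry members: full series before Sept 1
            idx_complete = np.flatnonzero(complete)
            if idx_complete.size:
                mat = _sample_preentry_dates(rng, birth_ord[idx_complete], entry_ord, k)
                _emit(idx_complete, mat)

            idx_active = np.flatnonzero(active)
            n_act = idx_active.size
            if n_act and at_entry:
                mat = _sample_preentry_dates(rng, birth_ord[idx_active], entry_ord, at_entry)
                _emit(idx_active, mat)

            if n_act and pending:
                q = _hazard_matrix(config, cohort, series, pending, n_months)
                dose_month = np.full((n_act, pending), -1, dtype=np.int64)
                cur = np.zeros(n_act, dtype=np.int64)
                for t in range(n_months):
                    draws = rng.random(n_act)
                    attempting = cur < pending
                    p = np.where(attempting, q[np.minimum(cur, pending - 1), t], 0.0)
                    hit = attempting & (draws < p)
                    dose_month[hit, cur[hit]] = t
                    cur[hit] += 1
                day_matrix = np.full((n_act, pending), -1, dtype=np.int64)
                for j in range(pending):
                    got = dose_month[:, j] >= 0
                    if not got.any():
                        continue
                    months = entry + dose_month[got, j]
                    dims = np.array([days_in_month(int(m)) for m in months])
                    starts = np.array([month_start(int(m)).toordinal() for m in months])
                    day_matrix[got, j] = starts + np.floor(
                        rng.random(int(got.sum())) * dims
                    ).astype(np.int64)
                _emit(idx_active, day_matrix)

    return SimulationOutput(
        persons=persons,
        enrollments=enrollments,
        doses=doses,
        ground_truth=analytic_ground_truth(config),
    )


# ---------------------------------------------------------------------------
# The default study conditions (a stylized provincial program)


def default_simulation_config(seed: int, cohort_size: int = 5000) -> SimulationConfig:
    """Default synthetic study: 15 cohorts, six series, a Mar 2020 – Jun 2021
    disruption at δ=0.2, and multi-year catch-up tails.

    Hazards and refuser/entry-complete fractions are stylized to land the
    prepandemic cohorts near the coverage levels typical of an established
    school-based program (roughly 85–90% for single-dose adolescent series,
    65–80% for multi-dose series, Grade 1 entry coverage near 75%).
    """
    cohorts = []
    for program_grade in study.PROGRAM_GRADES:
        pre_grade, pre_year = study.PREPANDEMIC[program_grade]
        cohorts.append(
            CohortSim(
                grade=pre_grade,
                school_year=pre_year,
                size=cohort_size,
                role="prepandemic",
                program_grade=program_grade,
            )
        )
        for year in study.PANDEMIC_YEARS:
            cohorts.append(
                CohortSim(
                    grade=program_grade,
                    school_year=year,
                    size=cohort_size,
                    role="pandemic",
                    program_grade=program_grade,
                )
            )

    grade1_hazard = {m: 0.10 for m in range(1, 10)}  # Oct..June screening
    # school-clinic rounds; 2-dose cohorts use the first two schedules
    three_dose = [{1: 0.7, 2: 0.5}, {4: 0.7, 5: 0.5}, {8: 0.7, 9: 0.5}]
    adolescent = [{1: 0.7, 6: 0.6}]

    series = [
        SeriesSim(
            antigen_group="measles_containing",
            grade=1,
            required_doses={"default": 2},
            entry_complete_fraction=0.75,
            pending_doses=1,
            dose_hazards=[grade1_hazard],
            catchup_hazard=0.010,
            refuser_fraction=0.055,
            product_codes=["MMR", "MMRV"],
        ),
        SeriesSim(
            antigen_group="pertussis_containing",
            grade=1,
            required_doses={"default": 5},
            entry_complete_fraction=0.73,
            pending_doses=1,
            dose_hazards=[grade1_hazard],
            catchup_hazard=0.010,
            refuser_fraction=0.075,
            product_codes=["DTaP-IPV", "DTaP-IPV-Hib"],
        ),
        SeriesSim(
            antigen_group="hpv",
            grade=6,
            required_doses={"2017-2018": 3, "default": 2},
            dose_hazards=three_dose,  # 2-dose cohorts use the first two schedules
            catchup_hazard=0.080,
            refuser_fraction=0.22,
            product_codes=["HPV9"],
        ),
        SeriesSim(
            antigen_group="hepatitis_b",
            grade=6,
            required_doses={"2017-2018": 3, "default": 2},
            dose_hazards=three_dose,
            catchup_hazard=0.080,
            refuser_fraction=0.15,
            product_codes=["HBV"],
        ),
        SeriesSim(
            antigen_group="men_acyw",
            grade=9,
            required_doses={"default": 1},
            dose_hazards=adolescent,
            catchup_hazard=0.030,
            refuser_fraction=0.10,
            product_codes=["MenACYW"],
        ),
        SeriesSim(
            antigen_group="pertussis_containing",
            grade=9,
            required_doses={"default": 1},
            dose_hazards=adolescent,
            catchup_hazard=0.030,
            refuser_fraction=0.09,
            product_codes=["Tdap"],
        ),
    ]

    return SimulationConfig(
        seed=seed,
        cohorts=cohorts,
        series=series,
        disruption_window=("2020-03", "2021-06"),
        disruption_multiplier=0.2,
        observation_end=study.OBSERVATION_END,
        online_only_fraction=0.01,
        censor_fraction=0.005,
    )
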