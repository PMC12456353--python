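"""Shared fixtures: a tiny hand-written registry and small simulated studies."""

from __future__ import annotations

import datetime as dt

import pytest

from sbip_catchup.cohort_builder import CohortSpec
from sbip_catchup.registry_model import (
    DoseRecord,
    EnrollmentRecord,
    PersonRecord,
    SeriesSpec,
    write_table,
)
from sbip_catchup.synthetic_registry import (
    CohortSim,
    SeriesSim,
    SimulationConfig,
    simulate,
)


@pytest.fixture
def tiny_registry():
    """Two persons, two enrollments, three doses — hand-checkable."""
    persons = [
        PersonRecord("A1", dt.date(2013, 10, 4), None, "F"),
        PersonRecord("A2", dt.date(2014, 2, 11), None, "M"),
    ]
    enrollments = [
        EnrollmentRecord("A1", "2019-2020", 1, "S01-000", frozenset()),
        EnrollmentRecord("A2", "2019-2020", 1, "S01-000", frozenset()),
    ]
    doses = [
        DoseRecord("A1", "measles_containing", "MMR", dt.date(2014, 11, 2)),
        DoseRecord("A1", "measles_containing", "MMRV", dt.date(2019, 11, 20)),
        DoseRecord("A2", "measles_containing", "MMR", dt.date(2015, 3, 1)),
    ]
    return persons, enrollments, doses


@pytest.fixture
def tiny_registry_paths(tiny_registry, tmp_path):
    persons, enrollments, doses = tiny_registry
    paths = (tmp_path / "persons.csv", tmp_path / "enrollments.csv", tmp_path / "doses.csv")
    write_table(persons, paths[0], PersonRecord)
    write_table(enrollments, paths[1], EnrollmentRecord)
    write_table(doses, paths[2], DoseRecord)
    return paths


def single_dose_config(
    seed: int = 11,
    n: int = 200,
    refuser_fraction: float = 0.0,
    entry_complete: float = 0.0,
    hazards: dict[int, float] | None = None,
    delta: float = 1.0,
    catchup: float = 0.0,
    window: tuple[str, str] = ("2020-03", "2021-06"),
    school_year: str = "2019-2020",
    observation_end: str = "2024-07",
    required: int = 1,
    pending: int | None = None,
    dose_hazards: list[dict[int, float]] | None = None,
    role: str = "pandemic",
) -> SimulationConfig:
    """One Grade 9 cohort, one series — the smallest useful study."""
    return SimulationConfig(
        seed=seed,
        cohorts=[CohortSim(grade=9, school_year=school_year, size=n, role=role)],
        series=[
            SeriesSim(
                antigen_group="men_acyw",
                grade=9,
                required_doses={"default": required},
                entry_complete_fraction=entry_complete,
                pending_doses=pending,
                dose_hazards=dose_hazards if dose_hazards is not None else [hazards or {1: 0.5}],
                catchup_hazard=catchup,
                refuser_fraction=None,
            )
        ],
        refuser_fraction=refuser_fraction,
        disruption_window=window,
        disruption_multiplier=delta,
        observation_end=observation_end,
    )


@pytest.fixture(scope="session")
def grade9_spec():
    return CohortSpec(
        grade=9,
        school_year="2019-2020",
        role="pandemic",
        age_window=(13, 15),
        reference_month="2020-07",
        coverage_start_month="2020-07",
        observation_end="2024-07",
        program_grade=9,
    )


@pytest.fixture(scope="session")
def men_series():
    return SeriesSpec(
        antigen_group="men_acyw",
        grade=9,
        required_doses_by_cohort_year={"default": 1},
        label="MenC-ACYW",
    )


@pytest.fixture(scope="session")
def simulated_small_study():
    """Five Grade 6 cohorts, two 2-dose series, disrupted — shared across tests."""
    config = SimulationConfig(
        seed=4242,
        cohorts=[
            CohortSim(grade=5, school_year="2017-2018", size=500, role="prepandemic", program_grade=6),
            CohortSim(grade=6, school_year="2019-2020", size=500),
            CohortSim(grade=6, school_year="2020-2021", size=500),
            CohortSim(grade=6, school_year="2021-2022", size=500),
            CohortSim(grade=6, school_year="2022-2023", size=500),
        ],
        series=[
            SeriesSim(
                antigen_group="hpv",
                grade=6,
                required_doses={"2017-2018": 3, "default": 2},
                dose_hazards=[{1: 0.7, 2: 0.5}, {4: 0.7, 5: 0.5}, {8: 0.7, 9: 0.5}],
                catchup_hazard=0.05,
                refuser_fraction=0.2,
            ),
            SeriesSim(
                antigen_group="hepatitis_b",
                grade=6,
                required_doses={"2017-2018": 3, "default": 2},
                dose_hazards=[{1: 0.7, 2: 0.5}, {4: 0.7, 5: 0.5}, {8: 0.7, 9: 0.5}],
                catchup_hazard=0.05,
                refuser_fraction=0.12,
            ),
        ],
        disruption_window=("2020-03", "2021-06"),
        disruption_multiplier=0.2,
        observation_end="2024-07",
    )
    return config, simulate(config)
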