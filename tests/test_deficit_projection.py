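"""Deficit arithmetic, projection to years of catch-up effort, and
ground-truth recovery on synthetic studies."""

from __future__ import annotations

import pytest

from sbip_catchup.alberta import REPORTED_DEFICIT_INPUTS, REPORTED_GRADE_TOTALS
from sbip_catchup.cohort_builder import build_cohorts
from sbip_catchup.coverage_engine import cumulative_coverage, doses_frame
from sbip_catchup.deficit_projection import (
    cumulative_deficit,
    deficit_table,
    expected_vaccinated,
    round_years,
    time_to_clear,
)
from sbip_catchup.administration_volume import period_volumes
from sbip_catchup.errors import ConfigError
from sbip_catchup.pipeline import _registry_from_simulation, _specs_from_simulation
from sbip_catchup.synthetic_registry import simulate

from conftest import single_dose_config


@pytest.mark.parametrize(
    "coverage, sizes, expected",
    [
        (1.0, [100, 200], 300),
        (0.0, [100, 200], 0),
        (0.905, [40000, 41000, 42000, 43000], 150230),  # 0.905 × 166000
        (0.5, [1], 1),  # half-up rounding of 0.5
    ],
)
def test_expected_vaccinated(coverage, sizes, expected):
    assert expected_vaccinated(coverage, sizes) == expected


def test_expected_vaccinated_rounds_once_at_the_end():
    # per-cohort rounding would give 2; a single final rounding gives 1
    assert expected_vaccinated(0.4999, [1, 1]) == 1


@pytest.mark.parametrize(
    "expected, observed, deficit",
    [(198_332, 183_132, -15_200), (167_633, 161_700, -5_933), (100, 100, 0)],
)
def test_cumulative_deficit(expected, observed, deficit):
    assert cumulative_deficit(expected, observed) == deficit


def test_all_reported_deficit_rows_reproduce():
    deficits = [
        cumulative_deficit(r.expected_vaccinated, r.observed_vaccinated)
        for r in REPORTED_DEFICIT_INPUTS
    ]
    assert deficits == [-15_200, -14_789, -5_933, -9_261, -16_435, -17_434]


def test_reported_grade_totals_sum():
    assert sum(REPORTED_GRADE_TOTALS.values()) == 799_961


@pytest.mark.parametrize(
    "deficit, uptake, years",
    [(0, 50, 0.0), (100, 50, 0.0), (-100, 50, 2.0), (-75, 1000, 0.075)],
)
def test_time_to_clear(deficit, uptake, years):
    assert time_to_clear(deficit, uptake) == pytest.approx(years)


def test_time_to_clear_undefined_without_uptake():
    with pytest.raises(ConfigError):
        time_to_clear(-10, 0)
    assert time_to_clear(10, 0) == 0.0  # no shortfall, no horizon needed


def test_round_years_precision_rule():
    assert round_years(0.373) == 0.37
    assert round_years(5.647) == 5.6
    assert round_years(1.04) == 1.0


def _study_tables(config):
    out = simulate(config)
    specs = _specs_from_simulation(config, config.observation_end)
    cohorts = build_cohorts(out.persons, out.enrollments, specs)
    registry = _registry_from_simulation(config)
    frame = doses_frame(out.doses)
    coverage, volumes = [], []
    study_range = ("2017-09", config.observation_end)
    for cohort in cohorts:
        for series in registry[cohort.spec.program_grade]:
            coverage.extend(cumulative_coverage(cohort, frame, series))
            volumes.extend(period_volumes(cohort, out.doses, series, study_range))
    return out, cohorts, registry, coverage, volumes, study_range


def test_deficit_table_identity_and_ordering(simulated_small_study):
    config, _ = simulated_small_study
    _, cohorts, registry, coverage, volumes, study_range = _study_tables(config)
    reports = deficit_table(coverage, volumes, cohorts, registry, study_range)
    assert len(reports) == 2  # hpv + hepatitis_b for the one simulated grade
    assert [r.antigen_group for r in reports] == ["hpv", "hepatitis_b"]
    for r in reports:
        assert r.cumulative_deficit == r.observed_vaccinated - r.expected_vaccinated
        assert r.min_years_to_clear <= r.avg_years_to_clear
        assert r.max_annual_uptake >= r.avg_annual_uptake


def null_study_config(n: int, seed: int):
    """An exchangeable δ=1 study: identical 2-dose requirements in every
    cohort year and a catch-up hazard strong enough that all cohorts reach
    their asymptote before study end (otherwise unequal follow-up time alone
    produces a real, nonzero deficit)."""
    from sbip_catchup.synthetic_registry import CohortSim, SeriesSim, SimulationConfig

    return SimulationConfig(
        seed=seed,
        cohorts=[
            CohortSim(grade=5, school_year="2017-2018", size=n,
                      role="prepandemic", program_grade=6),
            CohortSim(grade=6, school_year="2019-2020", size=n),
            CohortSim(grade=6, school_year="2020-2021", size=n),
            CohortSim(grade=6, school_year="2021-2022", size=n),
            CohortSim(grade=6, school_year="2022-2023", size=n),
        ],
        series=[
            SeriesSim(
                antigen_group="hpv", grade=6, required_doses={"default": 2},
                dose_hazards=[{1: 0.7, 2: 0.5}, {4: 0.7, 5: 0.5}],
                catchup_hazard=0.25, refuser_fraction=0.2,
            ),
            SeriesSim(
                antigen_group="hepatitis_b", grade=6, required_doses={"default": 2},
                dose_hazards=[{1: 0.7, 2: 0.5}, {4: 0.7, 5: 0.5}],
                catchup_hazard=0.25, refuser_fraction=0.12,
            ),
        ],
        disruption_multiplier=1.0,
        observation_end="2024-07",
    )


def test_null_study_deficits_within_sampling_noise():
    """δ=1 with exchangeable cohorts: every deficit is within 3 SE of zero."""
    null = null_study_config(n=500, seed=777)
    _, cohorts, registry, coverage, volumes, study_range = _study_tables(null)
    reports = deficit_table(coverage, volumes, cohorts, registry, study_range)
    for r in reports:
        pandemic = [
            c.size for c in cohorts
            if c.spec.role == "pandemic" and c.spec.program_grade == r.grade
        ]
        [n_pre] = [
            c.size for c in cohorts
            if c.spec.role == "prepandemic" and c.spec.program_grade == r.grade
        ]
        total = sum(pandemic)
        p = r.expected_vaccinated / total
        # expected inherits the prepandemic estimate's noise scaled by the
        # pooled size; observed adds its own binomial noise
        sd = (p * (1 - p) * (total**2 / n_pre + total)) ** 0.5
        assert abs(r.cumulative_deficit) <= 3 * sd


def test_known_shortfall_recovered_within_three_se():
    """A cohort with an engineered unrecovered shortfall f=0.08: the estimated
    deficit lands within 3 SE of −f·n."""
    n = 5000
    shared = dict(dose_hazards=[{1: 0.8}], catchup=0.0, refuser_fraction=0.1,
                  window=("2019-09", "2020-08"), observation_end="2022-07")
    # δ chosen so the end-of-study gap is exactly 0.08:
    # C_ref = 0.9*0.8 = 0.72; C_disrupted = 0.72 - 0.08 = 0.64 -> h·δ = 0.64/0.9
    delta = (0.64 / 0.9) / 0.8
    disrupted = single_dose_config(seed=21, n=n, delta=delta, **shared)
    reference = single_dose_config(seed=23, n=n, delta=1.0, school_year="2018-2019",
                                   role="prepandemic", **shared)
    config = disrupted.model_copy(
        update={"cohorts": reference.cohorts + disrupted.cohorts}
    )
    out, cohorts, registry, coverage, volumes, study_range = _study_tables(config)
    truth = out.ground_truth.deficit("G9_2019-2020", "men_acyw")
    assert truth.reference_coverage_end - truth.expected_coverage_end == pytest.approx(0.08)
    # no catch-up phase exists here, so assemble the deficit from its parts
    pre_end = max(
        p.proportion for p in coverage if p.cohort_id == "G9_2018-2019"
    )
    pan_end = max(
        (p for p in coverage if p.cohort_id == "G9_2019-2020"),
        key=lambda p: p.calendar_month,
    )
    deficit = cumulative_deficit(expected_vaccinated(pre_end, [n]), pan_end.n_covered)
    se = (n * (0.72 * 0.28 + 0.64 * 0.36)) ** 0.5
    assert deficit == pytest.approx(-0.08 * n, abs=3 * se)


def test_scale_equivariance_of_deficits(simulated_small_study):
    config, _ = simulated_small_study
    doubled = config.model_copy(
        update={"cohorts": [c.model_copy(update={"size": c.size * 2}) for c in config.cohorts]}
    )
    _, cohorts1, registry, cov1, vol1, rng1 = _study_tables(config)
    _, cohorts2, _, cov2, vol2, rng2 = _study_tables(doubled)
    r1 = deficit_table(cov1, vol1, cohorts1, registry, rng1)
    r2 = deficit_table(cov2, vol2, cohorts2, registry, rng2)
    for a, b in zip(r1, r2):
        assert b.expected_vaccinated == pytest.approx(2 * a.expected_vaccinated, rel=0.1)
        assert b.observed_vaccinated == pytest.approx(2 * a.observed_vaccinated, rel=0.1)
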