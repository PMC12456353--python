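"""Cumulative coverage, Wilson intervals, and counterfactual differences."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbip_catchup.cohort_builder import Cohort, build_cohorts, default_specs
from sbip_catchup.coverage_engine import (
    binomial_ci,
    coverage_difference,
    cumulative_coverage,
    doses_frame,
    months_from_reference,
)
from sbip_catchup.dates import month_end, month_label, parse_month
from sbip_catchup.errors import ConfigError
from sbip_catchup.registry_model import DoseRecord, SeriesSpec
from sbip_catchup.synthetic_registry import analytic_coverage, simulate

from conftest import single_dose_config


def _cohort(spec, member_ids):
    return Cohort(spec=spec, members=tuple(sorted(member_ids)), exclusion_tally={})


# ---------------------------------------------------------------------------
# months_from_reference


@pytest.mark.parametrize(
    "calendar_month, expected",
    [("2021-07", 12), ("2020-07", 0), ("2019-09", -10), ("2024-07", 48)],
)
def test_months_from_reference_for_2019_2020_cohort(calendar_month, expected):
    spec = [s for s in default_specs() if s.program_grade == 1][1]  # 2019-2020
    assert spec.school_year == "2019-2020"
    assert months_from_reference(spec, calendar_month) == expected


# ---------------------------------------------------------------------------
# Wilson interval


def test_wilson_bounds_at_extremes():
    low, high = binomial_ci(0, 50)
    assert low == 0.0 and high < 0.1
    low, high = binomial_ci(50, 50)
    assert high == 1.0 and low > 0.9


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact interval by bisecting the binomial tail probabilities."""
    alpha = 1.0 - level

    def tail_ge(p):  # P(X >= k)
        return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))

    def tail_le(p):  # P(X <= k)
        return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))

    def bisect(f, target, lo, hi):
        for _ in range(80):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    low = 0.0 if k == 0 else bisect(tail_ge, alpha / 2, 0.0, 1.0)
    high = 1.0 if k == n else bisect(lambda p: -tail_le(p), -alpha / 2, 0.0, 1.0)
    return low, high


def test_wilson_close_to_exact_interval():
    w_low, w_high = binomial_ci(70, 100)
    e_low, e_high = _clopper_pearson(70, 100)
    assert w_low == pytest.approx(e_low, abs=0.03)
    assert w_high == pytest.approx(e_high, abs=0.03)


def test_wilson_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        binomial_ci(0, 0)
    with pytest.raises(ValueError):
        binomial_ci(5, 3)


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=1, max_value=500), st.data())
def test_wilson_contains_point_estimate(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    low, high = binomial_ci(k, n)
    assert 0.0 <= low <= k / n <= high <= 1.0


def test_wilson_calibration_covers_true_p():
    """95% Wilson intervals cover p=0.7 in at least 93% of 2000 draws (n=200)."""
    rng = np.random.default_rng(20250901)
    draws = rng.binomial(200, 0.7, size=2000)
    covered = 0
    for k in draws:
        low, high = binomial_ci(int(k), 200)
        covered += low <= 0.7 <= high
    assert covered / 2000 >= 0.93


# ---------------------------------------------------------------------------
# cumulative coverage


def test_unvaccinated_cohort_has_zero_coverage(grade9_spec, men_series):
    cohort = _cohort(grade9_spec, [f"P{i}" for i in range(10)])
    points = cumulative_coverage(cohort, [], men_series, months=["2020-07", "2021-07"])
    assert [p.proportion for p in points] == [0.0, 0.0]
    assert all(p.ci_low == 0.0 for p in points)


def test_threshold_reached_at_second_dose_month(grade9_spec):
    series = SeriesSpec("hpv", 9, {"default": 2})
    cohort = _cohort(grade9_spec, ["P1", "P2"])
    doses = [
        DoseRecord("P1", "hpv", "HPV9", dt.date(2019, 10, 5)),
        DoseRecord("P1", "hpv", "HPV9", dt.date(2020, 4, 12)),
        DoseRecord("P2", "hpv", "HPV9", dt.date(2019, 10, 5)),
    ]
    months = ["2019-10", "2020-03", "2020-04", "2020-12"]
    points = cumulative_coverage(cohort, doses, series, months=months)
    assert [p.n_covered for p in points] == [0, 0, 1, 1]
    # at the 1+ dose threshold both members count from October
    one_plus = cumulative_coverage(cohort, doses, series, months=months, dose_threshold=1)
    assert [p.n_covered for p in one_plus] == [2, 2, 2, 2]


def test_min_interval_rule_discards_early_second_dose(grade9_spec):
    """With a 28-day minimum interval, a second dose 10 days after the first
    does not complete the series; the default (no rule) counts it."""
    strict = SeriesSpec("hpv", 9, {"default": 2}, min_interval_days=28)
    lax = SeriesSpec("hpv", 9, {"default": 2})
    cohort = _cohort(grade9_spec, ["P1"])
    doses = [
        DoseRecord("P1", "hpv", "HPV9", dt.date(2019, 10, 1)),
        DoseRecord("P1", "hpv", "HPV9", dt.date(2019, 10, 11)),
        DoseRecord("P1", "hpv", "HPV9", dt.date(2020, 2, 1)),
    ]
    months = ["2019-10", "2020-02"]
    assert [
        p.n_covered for p in cumulative_coverage(cohort, doses, lax, months=months)
    ] == [1, 1]
    assert [
        p.n_covered for p in cumulative_coverage(cohort, doses, strict, months=months)
    ] == [0, 1]


def test_empty_cohort_is_an_error(grade9_spec, men_series):
    with pytest.raises(ConfigError, match="empty"):
        cumulative_coverage(_cohort(grade9_spec, []), [], men_series)


def _brute_force_counts(cohort, doses, antigen, threshold, months):
    counts = []
    for label in months:
        cutoff = month_end(parse_month(label))
        covered = 0
        for pid in cohort.members:
            n = sum(
                1
                for d in doses
                if d.person_id == pid
                and d.antigen_group == antigen
                and d.administration_date <= cutoff
            )
            covered += n >= threshold
        counts.append(covered)
    return counts


def test_coverage_matches_per_person_recount_on_synthetic_study(simulated_small_study):
    """Vectorized counting equals a brute-force recount over all
    (member, month) pairs, exactly."""
    config, out = simulated_small_study
    from sbip_catchup.pipeline import _registry_from_simulation, _specs_from_simulation

    specs = _specs_from_simulation(config, config.observation_end)
    cohorts = build_cohorts(out.persons, out.enrollments, specs)
    registry = _registry_from_simulation(config)
    frame = doses_frame(out.doses)
    months = [month_label(m) for m in range(parse_month("2020-07"), parse_month("2024-07") + 1, 7)]
    for cohort in cohorts[:2]:  # prepandemic + first pandemic cohort
        for series in registry[6]:
            threshold = series.required_doses(cohort.spec.school_year)
            points = cumulative_coverage(cohort, frame, series, months=months)
            expected = _brute_force_counts(
                cohort, out.doses, series.antigen_group, threshold, months
            )
            assert [p.n_covered for p in points] == expected


def test_coverage_is_monotone_and_threshold_ordered(simulated_small_study):
    config, out = simulated_small_study
    from sbip_catchup.pipeline import _registry_from_simulation, _specs_from_simulation

    specs = _specs_from_simulation(config, config.observation_end)
    cohorts = build_cohorts(out.persons, out.enrollments, specs)
    series = _registry_from_simulation(config)[6][0]
    frame = doses_frame(out.doses)
    cohort = cohorts[1]
    complete = cumulative_coverage(cohort, frame, series)
    one_plus = cumulative_coverage(cohort, frame, series, dose_threshold=1)
    props = [p.proportion for p in complete]
    assert all(b >= a for a, b in zip(props, props[1:]))
    assert all(o.proportion >= c.proportion for o, c in zip(one_plus, complete))


# ---------------------------------------------------------------------------
# coverage differences


def _point(spec, series, m, k, n):
    [p] = cumulative_coverage(
        _cohort(spec, [f"Q{i}" for i in range(n)]),
        [
            DoseRecord(f"Q{i}", series.antigen_group, "X", dt.date(2020, 1, 1))
            for i in range(k)
        ],
        series,
        months=[month_label(parse_month(spec.reference_month) + m)],
    )
    return p


def test_identical_series_difference_is_zero(grade9_spec, men_series):
    pts = [_point(grade9_spec, men_series, m, 30, 60) for m in range(3)]
    diffs = coverage_difference(pts, pts)
    assert all(d.diff_pp == 0.0 for d in diffs)
    assert all(d.ci_low < 0.0 < d.ci_high for d in diffs)


def test_difference_interval_matches_resampling_oracle(grade9_spec, men_series):
    """Wald CI half-width for p1=p2=0.5, n=100 each vs a 1e5-draw Monte Carlo
    percentile oracle, within 0.5 pp."""
    a = _point(grade9_spec, men_series, 0, 50, 100)
    b = _point(grade9_spec, men_series, 0, 50, 100)
    [d] = coverage_difference([a], [b])
    half_width = (d.ci_high - d.ci_low) / 2
    rng = np.random.default_rng(77)
    sims = (rng.binomial(100, 0.5, 10**5) - rng.binomial(100, 0.5, 10**5)) / 100
    lo, hi = np.percentile(sims, [2.5, 97.5])
    mc_half = 100 * (hi - lo) / 2
    assert half_width == pytest.approx(mc_half, abs=0.5)


def test_disjoint_months_rejected(grade9_spec, men_series):
    a = [_point(grade9_spec, men_series, 0, 5, 10)]
    b = [_point(grade9_spec, men_series, 3, 5, 10)]
    with pytest.raises(ConfigError, match="overlap"):
        coverage_difference(a, b)


def test_null_disruption_centers_differences_at_zero():
    """With δ=1 the pandemic cohort's coverage distribution equals the
    reference cohort's: mean |difference| stays within 2 SE of zero."""
    base = single_dose_config(seed=303, n=5000, dose_hazards=[{1: 0.5, 2: 0.4}],
                              catchup=0.02, refuser_fraction=0.1, delta=1.0)
    ref = single_dose_config(seed=909, n=5000, dose_hazards=[{1: 0.5, 2: 0.4}],
                             catchup=0.02, refuser_fraction=0.1, delta=1.0,
                             school_year="2018-2019", role="prepandemic")
    from sbip_catchup.pipeline import _registry_from_simulation, _specs_from_simulation

    series = _registry_from_simulation(base)[9][0]
    out_a, out_b = simulate(base), simulate(ref)
    [spec_a] = _specs_from_simulation(base, "2024-07")
    [spec_b] = _specs_from_simulation(ref, "2024-07")
    cohort_a = build_cohorts(out_a.persons, out_a.enrollments, [spec_a])[0]
    cohort_b = build_cohorts(out_b.persons, out_b.enrollments, [spec_b])[0]
    pa = cumulative_coverage(cohort_a, out_a.doses, series)
    pb = cumulative_coverage(cohort_b, out_b.doses, series)
    diffs = coverage_difference(pa, pb)
    se_pp = [(d.ci_high - d.ci_low) / (2 * 1.959964) for d in diffs]
    mean_abs = np.mean([abs(d.diff_pp) for d in diffs])
    assert mean_abs < 2 * np.mean(se_pp)


def test_disrupted_cohort_difference_recovers_analytic_gap():
    """δ=0.2 over the scheduled window: the end-of-grade-year difference is
    within 3 SE of the analytic coverage gap from the generative model."""
    kwargs = dict(n=5000, dose_hazards=[{1: 0.6, 6: 0.5}], catchup=0.01,
                  refuser_fraction=0.1, window=("2019-09", "2020-08"))
    disrupted = single_dose_config(seed=11, delta=0.2, **kwargs)
    reference = single_dose_config(seed=13, delta=1.0, school_year="2018-2019",
                                   role="prepandemic", **kwargs)
    from sbip_catchup.pipeline import _registry_from_simulation, _specs_from_simulation

    series = _registry_from_simulation(disrupted)[9][0]
    out_d, out_r = simulate(disrupted), simulate(reference)
    [spec_d] = _specs_from_simulation(disrupted, "2024-07")
    [spec_r] = _specs_from_simulation(reference, "2024-07")
    cohort_d = build_cohorts(out_d.persons, out_d.enrollments, [spec_d])[0]
    cohort_r = build_cohorts(out_r.persons, out_r.enrollments, [spec_r])[0]
    pd_ = cumulative_coverage(cohort_d, out_d.doses, series, months=["2020-07"])
    pr_ = cumulative_coverage(cohort_r, out_r.doses, series, months=["2019-07"])
    [diff] = coverage_difference(pd_, pr_)
    c_d = analytic_coverage(disrupted, "G9_2019-2020", "men_acyw", "2020-07")
    c_r = analytic_coverage(reference, "G9_2018-2019", "men_acyw", "2019-07")
    analytic_gap_pp = 100 * (c_d - c_r)
    se_pp = 100 * math.sqrt(c_d * (1 - c_d) / 5000 + c_r * (1 - c_r) / 5000)
    assert diff.diff_pp == pytest.approx(analytic_gap_pp, abs=3 * se_pp)
    assert diff.diff_pp < -10  # the disruption leaves a visible gap
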