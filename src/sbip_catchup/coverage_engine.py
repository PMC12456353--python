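"""Monthly cumulative coverage, Wilson binomial intervals, and counterfactual
coverage differences.

Cumulative coverage of a closed cohort at calendar month *t* is the fraction
of members holding at least the series' dose threshold by the last day of
*t*; the denominator is fixed at cohort size for all months. Differences
align a pandemic cohort with its prepandemic counterfactual on months from
the shared follow-up reference (July of each cohort's grade-year end) and
carry a Wald interval from the two independent binomial proportions, in
percentage points.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .cohort_builder import Cohort, CohortSpec
from .dates import month_end, month_label, parse_month
from .errors import ConfigError
from .registry_model import DoseRecord, SeriesSpec


@dataclasses.dataclass(frozen=True)
class CoveragePoint:
    cohort_id: str
    antigen_group: str
    dose_threshold: int
    calendar_month: str
    months_from_reference: int
    n_covered: int
    n_total: int
    proportion: float
    ci_low: float
    ci_high: float

    KEY = ("cohort_id", "antigen_group", "dose_threshold", "calendar_month")


@dataclasses.dataclass(frozen=True)
class CoverageDifferencePoint:
    """Pandemic-minus-prepandemic coverage at one aligned month, in pp."""

    cohort_id: str  # the pandemic cohort
    antigen_group: str
    months_from_reference: int
    diff_pp: float
    ci_low: float
    ci_high: float

    KEY = ("cohort_id", "antigen_group", "months_from_reference")


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Endpoints are snapped to the exact Wilson values 0 (at k=0) and 1 (at
    k=n), and the interval always contains k/n.
    """
    if n < 1:
        raise ValueError("binomial_ci requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    low, high = proportion_confint(count=k, nobs=n, alpha=1.0 - level, method="wilson")
    low = 0.0 if k == 0 else max(0.0, float(low))
    high = 1.0 if k == n else min(1.0, float(high))
    return low, high


def months_from_reference(spec: CohortSpec, calendar_month: str) -> int:
    """Signed whole months from the cohort's reference (July of grade-year end)."""
    return parse_month(calendar_month) - parse_month(spec.reference_month)


def doses_frame(doses: Sequence[DoseRecord] | pd.DataFrame) -> pd.DataFrame:
    """Columnar view of dose records (person_id, antigen_group, administration_date)."""
    if isinstance(doses, pd.DataFrame):
        return doses
    return pd.DataFrame(
        {
            "person_id": [d.person_id for d in doses],
            "antigen_group": [d.antigen_group for d in doses],
            "administration_date": [d.administration_date for d in doses],
        }
    )


def attainment_dates(
    doses: pd.DataFrame,
    members: Sequence[str],
    antigen_group: str,
    threshold: int,
    min_interval_days: int = 0,
) -> pd.Series:
    """Per member, the date the k-th counted dose of the antigen was received.

    Members who never reach ``threshold`` doses are absent from the result.
    With ``min_interval_days > 0``, a dose only counts if at least that many
    days after the previously counted dose (greedy earliest-valid rule);
    the default counts doses exactly as recorded.
    """
    df = doses[
        doses["antigen_group"].eq(antigen_group)
        & doses["person_id"].isin(set(members))
    ]
    if df.empty:
        return pd.Series(dtype=object)
    ordered = df.sort_values(["person_id", "administration_date"], kind="mergesort")
    if min_interval_days <= 0:
        pos = ordered.groupby("person_id", sort=False).cumcount()
        kth = ordered[pos == threshold - 1]
        return kth.set_index("person_id")["administration_date"]
    out: dict[str, object] = {}
    for pid, group in ordered.groupby("person_id", sort=False):
        counted = 0
        last = None
        for d in group["administration_date"]:
            if last is None or (d - last).days >= min_interval_days:
                counted += 1
                last = d
                if counted == threshold:
                    out[pid] = d
                    break
    return pd.Series(out, dtype=object)


def cumulative_coverage(
    cohort: Cohort,
    doses: Sequence[DoseRecord] | pd.DataFrame,
    series: SeriesSpec,
    months: Sequence[str] | None = None,
    level: float = 0.95,
    dose_threshold: int | None = None,
) -> list[CoveragePoint]:
    """Cumulative monthly coverage with Wilson CIs for one cohort and series.

    ``months`` defaults to the cohort's coverage window (coverage start month
    through observation end). A dose counts toward month *t* when dated on or
    before the last calendar day of *t*.
    """
    n_total = cohort.size
    if n_total == 0:
        raise ConfigError(f"cohort {cohort.cohort_id} is empty; coverage undefined")
    threshold = (
        dose_threshold
        if dose_threshold is not None
        else series.dose_threshold(cohort.spec.school_year)
    )
    if months is None:
        start = parse_month(cohort.spec.coverage_start_month)
        end = parse_month(cohort.spec.observation_end)
        months = [month_label(m) for m in range(start, end + 1)]

    attain = attainment_dates(
        doses_frame(doses),
        cohort.members,
        series.antigen_group,
        threshold,
        series.min_interval_days,
    )
    attain_days = np.sort(np.array([d.toordinal() for d in attain], dtype=np.int64))

    points: list[CoveragePoint] = []
    for label in months:
        idx = parse_month(label)
        cutoff = month_end(idx).toordinal()
        k = int(np.searchsorted(attain_days, cutoff, side="right"))
        low, high = binomial_ci(k, n_total, level)
        points.append(
            CoveragePoint(
                cohort_id=cohort.cohort_id,
                antigen_group=series.antigen_group,
                dose_threshold=threshold,
                calendar_month=label,
                months_from_reference=months_from_reference(cohort.spec, label),
                n_covered=k,
                n_total=n_total,
                proportion=k / n_total,
                ci_low=low,
                ci_high=high,
            )
        )
    return points


def coverage_difference(
    pandemic_series: Sequence[CoveragePoint],
    prepandemic_series: Sequence[CoveragePoint],
    level: float = 0.95,
) -> list[CoverageDifferencePoint]:
    """Month-aligned coverage differences (pandemic − prepandemic), in pp.

    The 95% interval combines the standard errors of the two independent
    binomial proportions (Wald on the difference).
    """
    pan = {p.months_from_reference: p for p in pandemic_series}
    pre = {p.months_from_reference: p for p in prepandemic_series}
    shared = sorted(set(pan) & set(pre))
    if not shared:
        raise ConfigError("no overlapping months_from_reference between the two series")
    z = norm.ppf(0.5 + level / 2.0)
    out: list[CoverageDifferencePoint] = []
    for m in shared:
        a, b = pan[m], pre[m]
        p1, p2 = a.proportion, b.proportion
        se = np.sqrt(p1 * (1 - p1) / a.n_total + p2 * (1 - p2) / b.n_total)
        diff = 100.0 * (p1 - p2)
        half = 100.0 * z * float(se)
        out.append(
            CoverageDifferencePoint(
                cohort_id=a.cohort_id,
                antigen_group=a.antigen_group,
                months_from_reference=m,
                diff_pp=diff,
                ci_low=diff - half,
                ci_high=diff + half,
            )
        )
    return out
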