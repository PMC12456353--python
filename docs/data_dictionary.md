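# Data dictionary

Dates are ISO-8601 (`YYYY-MM-DD`); month keys are `YYYY-MM`; school-year
labels `YYYY-YYYY` denote Sept 1 of the first year through Aug 31 of the
second. Every table is CSV with a header row, sorted by the listed key.

## Input tables

### persons.csv — key: person_id
| column | type | meaning |
|---|---|---|
| person_id | string | opaque unique identifier |
| birth_date | date | |
| censor_date | date or empty | death/out-migration; empty = observed to study end |
| sex | string | reporting only; unused by the analysis |

### enrollments.csv — key: school_year, grade, person_id
| column | type | meaning |
|---|---|---|
| person_id | string | must resolve to persons.csv |
| school_year | label | e.g. `2019-2020` |
| grade | int | one of 1, 5, 6, 9 |
| school_id | string | opaque |
| exclusion_flags | `;`-separated list (may be empty) | subset of `online_only`, `postsecondary_or_continuing`, `summer_or_evening`, `on_reserve`, `lloydminster` |

At most one enrollment per person per school year.

### doses.csv — key: person_id, antigen_group, administration_date, product_code
| column | type | meaning |
|---|---|---|
| person_id | string | must resolve to persons.csv |
| antigen_group | label | one of the configured series groups, e.g. `measles_containing`, `pertussis_containing`, `hpv`, `hepatitis_b`, `men_acyw` |
| product_code | string | opaque product identifier (e.g. MMR vs MMRV); both measles products map to `measles_containing` upstream |
| administration_date | date | ≥ the person's birth date |

## Result tables

### cohorts.csv — key: cohort_id, person_id
One row per cohort member. `cohort_id` is `G<grade>_<school_year>`.

### exclusions.csv — key: cohort_id, reason
`count` of enrollments rejected from the cohort under each first-matching
`reason` (a flag name, `age`, `censoring`, or `repeat_enrollment`).

### coverage.csv — key: cohort_id, antigen_group, dose_threshold, calendar_month
| column | meaning |
|---|---|
| dose_threshold | doses required to count as covered (complete series, or 1 for the 1+ view) |
| months_from_reference | signed months since July of the grade-year end (Grade 1 rows start at −10) |
| n_covered, n_total | members at/above threshold by month end; cohort size |
| proportion, ci_low, ci_high | coverage with Wilson 95% bounds |

### coverage_diff.csv — key: cohort_id, antigen_group, months_from_reference
`diff_pp` = 100 × (pandemic − prepandemic) at the aligned month, with Wald
95% bounds in percentage points. `cohort_id` names the pandemic cohort.

### volume.csv — key: cohort_id, antigen_group, period_span, period_type
| column | meaning |
|---|---|
| period_type | `school_year` (Sept–June) or `summer` (July–Aug) |
| period_span | `2021-2022` for school years, `2022` for summers |
| routine_count | doses dated within the cohort's scheduled grade year |
| catchup_count | doses dated after June 30 of the grade year |

### deficits.csv — key: grade, antigen_group
| column | meaning |
|---|---|
| expected_vaccinated | prepandemic maximum coverage × pandemic cohort sizes, rounded half-up once |
| observed_vaccinated | covered pandemic-cohort members at study end |
| cumulative_deficit | observed − expected (negative = shortfall) |
| max_annual_uptake, avg_annual_uptake | catch-up doses per July–June window, pooled over the grade's pandemic cohorts |
| min_years_to_clear, avg_years_to_clear | shortfall ÷ max (resp. mean) annual uptake |

### ground_truth_coverage.csv / ground_truth_deficits.csv (synthetic runs)
Analytic expected coverage per cohort/series/month, and the analytic
end-of-study deficit of each cohort/series against a no-disruption (δ=1)
reference, from the generative hazard model.

### manifest.json
Tool version, SHA-256 of the resolved configuration, effective seed, and row
counts per written table.
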