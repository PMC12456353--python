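# Methods

## Setting and aim

School-based immunization programs (SBIPs) deliver scheduled vaccines to
whole grade cohorts: in the provincial design modeled here, Grade 1 receives
a catch-up opportunity for preschool series (second measles-containing dose,
fifth pertussis-containing dose), Grade 6 receives the 2-dose HPV and
hepatitis B series, and Grade 9 receives single doses of MenC-ACYW and an
adolescent pertussis booster. Pandemic-era school closures suppressed
delivery to the 2019-2020 through 2022-2023 grade-year cohorts. The package
quantifies that disruption and the subsequent recovery in three steps:
month-aligned cumulative coverage differences against a prepandemic
counterfactual cohort, routine vs catch-up dose-delivery volume, and
cumulative immunization deficits with a projection of the catch-up effort
needed to clear them.

## Cohorts

A grade-year cohort is the set of students enrolled in a target grade in one
school year (Sept 1 – Aug 31). Five annual cohorts per grade are analyzed:
one prepandemic baseline (2018-2019 for Grades 1 and 9; the Grade 5 cohort
of 2017-2018 for the Grade 6 program, because delivery moved from Grade 5 to
Grade 6 in 2018-2019 and no Grade 5/6 program ran that year) and the four
pandemic cohorts.

Eligibility: no exclusion flag (online/distance-only school, postsecondary
or continuing education, summer/evening school, on-reserve school, or the
Lloydminster border area — all arriving as precomputed booleans on the
enrollment record), attained age on Sept 1 inside the grade's window
(5–7 for Grade 1, 9–11 for Grade 5, 10–12 for Grade 6, 13–15 for Grade 9),
and no censoring (death or out-migration) on or before the end of the
observation period (July 2024). Decisions made where the rules are
underdetermined:

* **Age convention.** Attained (completed) years, with a birthday falling on
  Sept 1 counting as attained; a Feb 29 birthday is attained on Mar 1 in
  common years.
* **Exclusion precedence.** Flags, then age, then censoring, then repeat
  enrollment — fixed so the exclusion tallies are deterministic. Each
  rejected enrollment is counted under exactly one (the first matching)
  reason.
* **Repeaters.** A person enrolled in the same grade in two qualifying years
  stays in the first qualifying cohort; cohorts of one grade are therefore
  disjoint.

## Coverage

Cumulative coverage of a closed cohort at calendar month *t* is the fraction
of members holding at least the series' dose threshold by the last calendar
day of *t*. The denominator is fixed at cohort size for every month
(censored-at-entry members were already excluded). Complete-series
thresholds may differ by cohort year — 3 doses of HPV/hepatitis B for the
2017-2018 cohort vs 2 doses afterwards — and a 1+ dose view is computed
alongside every multi-dose series. Doses are counted as recorded; no
minimum-interval validity rule is applied (a configurable option exists but
is off by default), and same-day duplicates of one antigen are collapsed to
a single dose with a logged warning.

Coverage is reported from each cohort's follow-up axis: month 0 is July of
the grade-year's end, and Grade 1 tracking additionally starts at September
of the grade year (month −10), since Grade 1 members may arrive already
complete from preschool delivery.

**Intervals.** Single proportions carry a Wilson score interval at the
configured level (default 95%); the Wilson interval avoids the degenerate
zero-width intervals of the Wald form at the near-0/near-1 coverage levels
common in this setting, and its endpoints are exactly 0 at k=0 and 1 at
k=n. Differences between a pandemic and the prepandemic cohort, aligned on
months from reference and expressed in percentage points, carry a Wald
interval from the standard-error combination of the two independent
binomial proportions — the symmetric form matches how such differences are
conventionally reported. A calibration check (2000 simulated draws at
n=200, p=0.7) verifies ≥93% empirical coverage of the nominal 95% Wilson
interval.

## Administration volume

Each dose delivered to a cohort member is classified **routine** (dated
within Sept 1 – June 30 of the grade year) or **catch-up** (after June 30 of
the grade year). Doses predating the grade year — a Grade 1 member's
preschool doses — are left unclassified for volume purposes (logged), while
still counting toward coverage: volume measures program-era delivery,
coverage measures protection. Counts are dose counts, not person counts; a
`first_dose_only` switch counts series initiations instead, since bar-chart
conventions for multi-dose series vary.

Monthly counts collapse into school-year (Sept–June) and summer (Jul–Aug)
periods. **Annual catch-up uptake** pools catch-up doses across all pandemic
cohorts of a grade over July 1 – June 30 windows, starting at the first
pandemic cohort's reference July and dropping any incomplete trailing
window; both the maximum and the mean over complete windows are retained.

## Deficits and time to clear

For each grade and series, the **expected** number vaccinated is the
prepandemic cohort's maximum observed coverage (for a cumulative curve this
is its end-of-study value) multiplied by each pandemic cohort's size, summed
as reals and rounded half-up once. The **cumulative deficit** is observed −
expected at the end of the study (negative = shortfall). Dividing a
shortfall by annual catch-up uptake projects the additional years of
catch-up effort required: the *minimum* estimate uses the maximum annual
uptake, the *average* estimate the mean. Years are reported to 2 decimals
below one year and 1 decimal otherwise. When there is no shortfall the
projection is 0; a shortfall with zero observed catch-up uptake has no
defined horizon and raises an error rather than reporting infinity.

Two readings of "expected" are possible — coverage of the pandemic cohort
itself at study end (self-referential) or the prepandemic maximum applied to
pandemic cohort sizes; the latter is the counterfactual actually implied by
the deficit question and is what the implementation uses. Annual uptake is
computed per (grade, series), the finest reading consistent with
per-vaccine time-to-clear figures.

## Synthetic registry

The generator draws linked person/enrollment/dose tables from a
discrete-time monthly hazard model. Each member of a cohort is independently
a **refuser** (probability *r*, never vaccinated), **complete at entry**
(probability *prior*; holds the full series before Sept 1 — only meaningful
for Grade 1-style series), or **active**. An active member holds any
pre-program doses of the series (e.g. 4 of 5 pertussis doses at Grade 1
entry) and attempts at most one pending dose per month: during a dose's
scheduled months the success probability is the baseline hazard h_m,
multiplied by δ ∈ [0,1] when the calendar month lies in the disruption
window (Mar 2020 – Jun 2021 by default); after the dose's scheduled window
a constant per-month catch-up hazard c applies. Dose dates are uniform
within their month, birth dates uniform within the grade's age window, and
every draw comes from one seeded generator, so equal seeds give
byte-identical tables.

Because each member is a Markov chain over dose states, the exact expected
coverage curve C(t) = prior + (1 − prior − r) · P(active member complete by
t) is computed by dynamic programming over dose-state occupancy, and every
simulated study carries this curve — plus the analytic end-of-study deficit
against a δ=1 reference — as machine-checkable ground truth. The dynamic
program is validated against exhaustive enumeration of per-month outcome
paths on small cases, and the sampler against the analytic curve at
n=5000 within 3 standard errors.

**Default study conditions.** Fifteen cohorts (three programs × five years),
six series, δ=0.2 over Mar 2020 – Jun 2021. Hazards, refuser fractions, and
entry-complete fractions are stylized to land prepandemic cohorts near the
levels typical of an established SBIP — roughly 85–90% for single-dose
adolescent series, 65–80% complete for 2/3-dose series, Grade 1 entry
coverage near 75% — with per-series catch-up hazards (0.01/month for
Grade 1, 0.08 for Grade 6, 0.03 for Grade 9) that reproduce the observed
qualitative pattern: Grade 6 clearing its deficit within about a year of
effort, Grades 1 and 9 carrying multi-year deficits. Demo cohort size is
5000; tests use 300–5000 depending on what the check needs.

**What the generator does not emulate.** Entry-time (preschool) disruption:
the entry-complete fraction is a single probability per series, so later
Grade 1 cohorts do not arrive with depressed entry coverage as the most
recent real cohorts did. Also absent: sex effects, school-level clustering,
inter-dose interval rules, out-of-province doses, and time-varying refusal.
Passing tests therefore demonstrate correctness of the estimator machinery
under a faithful hazard model, not fidelity of any particular real-world
coverage level.

**A note on the δ=1 null.** "No disruption implies no deficit" holds only
for exchangeable cohorts evaluated at their asymptote. If the baseline
cohort has a different dose requirement (3 vs 2) or cohorts have unequal
catch-up time remaining at study end, a genuine nonzero difference exists
under δ=1 — the counterfactual design itself, not an estimator artifact.
Null-recovery checks therefore use identical per-year requirements and a
saturating catch-up hazard (0.25/month), so every cohort reaches its
asymptote 1 − r before study end.

## Numerical conventions

* Dates ISO-8601; month keys `YYYY-MM`; school years `YYYY-YYYY` meaning
  Sept 1 – Aug 31.
* All result tables are CSV with deterministic column and row order (sorted
  by each record's natural key); reals serialize at 10 significant digits,
  so write→read→write is byte-stable.
* Rounding half-up for expected counts (single final rounding); banker's
  rounding is deliberately avoided there to match surveillance-table
  conventions.
* Empty cohorts raise rather than emit divide-by-zero coverage; empty result
  lists write header-only files.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
complete in a few minutes on one CPU: demo study 5000/cohort (15 cohorts,
≈290k dose records), oracle-equivalence checks at 500/cohort, null and
shortfall recovery at 5000/cohort, calibration at 2000 replicate draws.

## Known limitations

* The Grade 9 pertussis series counts any recorded pertussis-containing
  dose toward its single-dose threshold; in real extracts (where Grade 9
  members carry childhood DTaP records) an age- or dose-number-based rule
  would be needed. Synthetic Grade 9 members hold only program-era doses,
  so the simplification is exact there.
* Annual catch-up uptake counts doses; where an "individuals vaccinated"
  reading is preferred for multi-dose series, use
  `volume_count_mode: first_dose_only`.
* The counterfactual ignores secular trends: the prepandemic cohort's own
  late catch-up partially overlaps the pandemic period, which tends to
  understate disruption effects — an inherent property of the design, not
  correctable within it.
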