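# Bundled demo study: a fully synthetic provincial registry run end to end.
#
# Exactly one of `inputs` / `simulate` / `simulate_default` may be present.
# `simulate_default` expands to the bundled study conditions: 15 grade-year
# cohorts (Grades 1, 6, 9 × five annual cohorts, 2017-2018 through 2022-2023),
# six vaccine series, a Mar 2020 - Jun 2021 disruption at multiplier 0.2, and
# per-series multi-year catch-up tails.
simulate_default:
  seed: 20240901        # master seed for every random draw in the study
  cohort_size: 5000     # members per grade-year cohort before exclusions

# Study end: coverage and deficits are evaluated through this month.
observation_end: "2024-07"

# Confidence level for every binomial interval (coverage and differences).
ci_level: 0.95

# Volume counting: "all_doses" counts every qualifying dose;
# "first_dose_only" counts series initiations instead.
volume_count_mode: all_doses

# To run on real extracts instead, replace simulate_default with:
# inputs:
#   persons: path/to/persons.csv
#   enrollments: path/to/enrollments.csv
#   doses: path/to/doses.csv
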