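"""Published Alberta surveillance counts used as worked-example inputs.

These are the reported grade-level cohort totals and end-of-study
expected/observed vaccinated counts for the Alberta school-based program's
2019-2023 pandemic cohorts (study end July 2024). They serve as fixed inputs
to the deficit arithmetic — the package recomputes the deficits from the
expected/observed pairs; it does not restate them.
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class ReportedCounts:
    grade: int
    vaccine: str
    antigen_group: str
    expected_vaccinated: int
    observed_vaccinated: int


#: End-of-study expected (counterfactual) and observed vaccinated counts,
#: pooled over the four pandemic cohorts of each grade.
REPORTED_DEFICIT_INPUTS: tuple[ReportedCounts, ...] = (
    ReportedCounts(1, "DTaP-IPV", "pertussis_containing", 198_332, 183_132),
    ReportedCounts(1, "MMR or MMRV", "measles_containing", 199_198, 184_409),
    ReportedCounts(6, "HPV", "hpv", 167_633, 161_700),
    ReportedCounts(6, "Hepatitis B", "hepatitis_b", 186_029, 176_768),
    ReportedCounts(9, "MenC-ACYW", "men_acyw", 180_871, 164_436),
    ReportedCounts(9, "Tdap", "pertussis_containing", 185_057, 167_623),
)

#: Children included across the five annual cohorts of each grade.
REPORTED_GRADE_TOTALS: dict[int, int] = {1: 270_603, 6: 273_163, 9: 256_195}
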