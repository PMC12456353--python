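"""Default study design: Alberta-style school-based immunization program.

Three program grades, five annual cohorts each (one prepandemic, four
pandemic). Grade 1 receives the second measles-containing and fifth
pertussis-containing dose (the grade-year acts as a catch-up window for
preschool series); Grade 6 receives the 2-dose HPV and hepatitis B series
(3-dose for the Grade 5 2017-2018 prepandemic cohort, delivered before the
program moved from Grade 5 to Grade 6); Grade 9 receives single doses of
MenC-ACYW and an adolescent pertussis booster.
"""

from __future__ import annotations

from .registry_model import SeriesSpec

#: Inclusive attained-age windows (years as of Sept 1) per enrolled grade.
AGE_WINDOWS: dict[int, tuple[int, int]] = {
    1: (5, 7),
    5: (9, 11),
    6: (10, 12),
    9: (13, 15),
}

PANDEMIC_YEARS: tuple[str, ...] = ("2019-2020", "2020-2021", "2021-2022", "2022-2023")

#: Prepandemic cohort per program grade: (enrolled grade, school year).
#: The Grade 6 program's baseline is the Grade 5 cohort of 2017-2018 (no
#: Grade 5/6 program ran in 2018-2019 when delivery moved grades).
PREPANDEMIC: dict[int, tuple[int, str]] = {
    1: (1, "2018-2019"),
    6: (5, "2017-2018"),
    9: (9, "2018-2019"),
}

OBSERVATION_END = "2024-07"  # study end: July 2024

PROGRAM_GRADES: tuple[int, ...] = (1, 6, 9)


def default_series_registry() -> dict[int, list[SeriesSpec]]:
    """The six tracked series, keyed by program grade."""
    return {
        1: [
            SeriesSpec(
                antigen_group="measles_containing",
                grade=1,
                required_doses_by_cohort_year={"default": 2},
                label="MMR or MMRV",
            ),
            SeriesSpec(
                antigen_group="pertussis_containing",
                grade=1,
                required_doses_by_cohort_year={"default": 5},
                label="DTaP-IPV",
            ),
        ],
        6: [
            SeriesSpec(
                antigen_group="hpv",
                grade=6,
                required_doses_by_cohort_year={"2017-2018": 3, "default": 2},
                label="HPV",
            ),
            SeriesSpec(
                antigen_group="hepatitis_b",
                grade=6,
                required_doses_by_cohort_year={"2017-2018": 3, "default": 2},
                label="Hepatitis B",
            ),
        ],
        9: [
            SeriesSpec(
                antigen_group="men_acyw",
                grade=9,
                required_doses_by_cohort_year={"default": 1},
                label="MenC-ACYW",
            ),
            SeriesSpec(
                antigen_group="pertussis_containing",
                grade=9,
                required_doses_by_cohort_year={"default": 1},
                label="Tdap",
            ),
        ],
    }
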