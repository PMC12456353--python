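"""Calendar arithmetic for school-year registries.

Conventions used throughout the package:

* calendar months are written ``"YYYY-MM"`` and handled internally as an
  absolute month index (``year * 12 + month - 1``) so that differences are
  plain integer subtraction;
* a school-year label ``"2019-2020"`` denotes Sept 1 2019 through Aug 31 2020;
* age is attained (completed) years: a child born Sept 1 turns the new age on
  Sept 1 itself; a Feb 29 birthday is attained on Mar 1 in common years.
"""

from __future__ import annotations

import calendar
import datetime as dt
import re

from .errors import RowError

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")
_SCHOOL_YEAR_RE = re.compile(r"^(\d{4})-(\d{4})$")


def parse_month(label: str) -> int:
    """Parse ``"YYYY-MM"`` into an absolute month index."""
    m = _MONTH_RE.match(label)
    if not m:
        raise RowError(f"invalid month label {label!r}; expected YYYY-MM")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise RowError(f"invalid month label {label!r}; month out of range")
    return year * 12 + month - 1


def month_label(index: int) -> str:
    """Inverse of :func:`parse_month`."""
    return f"{index // 12:04d}-{index % 12 + 1:02d}"


def month_index(year: int, month: int) -> int:
    return year * 12 + month - 1


def month_of(d: dt.date) -> int:
    """Absolute month index containing date ``d``."""
    return d.year * 12 + d.month - 1


def month_start(index: int) -> dt.date:
    return dt.date(index // 12, index % 12 + 1, 1)


def month_end(index: int) -> dt.date:
    """Last calendar day of the month."""
    year, month = index // 12, index % 12 + 1
    return dt.date(year, month, calendar.monthrange(year, month)[1])


def days_in_month(index: int) -> int:
    year, month = index // 12, index % 12 + 1
    return calendar.monthrange(year, month)[1]


def parse_school_year(label: str) -> tuple[int, int]:
    """Parse and validate a ``"YYYY-YYYY"`` school-year label (consecutive years)."""
    m = _SCHOOL_YEAR_RE.match(label)
    if not m:
        raise RowError(f"invalid school-year label {label!r}; expected YYYY-YYYY")
    first, second = int(m.group(1)), int(m.group(2))
    if second != first + 1:
        raise RowError(
            f"invalid school-year label {label!r}; second year must be first + 1"
        )
    return first, second


def school_year_label(start_year: int) -> str:
    return f"{start_year}-{start_year + 1}"


def school_year_entry(label: str) -> dt.date:
    """Sept 1 of the school year — enrollment reference date."""
    first, _ = parse_school_year(label)
    return dt.date(first, 9, 1)


def school_year_classes_end(label: str) -> dt.date:
    """June 30 of the school year — last day of in-school (routine) delivery."""
    _, second = parse_school_year(label)
    return dt.date(second, 6, 30)


def school_year_last_day(label: str) -> dt.date:
    """Aug 31 of the second year — end of the school-year span."""
    _, second = parse_school_year(label)
    return dt.date(second, 8, 31)


def reference_month(label: str) -> int:
    """July of the grade-year's end: month 0 of each cohort's follow-up axis."""
    _, second = parse_school_year(label)
    return month_index(second, 7)


def entry_month(label: str) -> int:
    """September of the grade year (start of Grade 1 coverage tracking)."""
    first, _ = parse_school_year(label)
    return month_index(first, 9)


def attained_age(birth: dt.date, on: dt.date) -> int:
    """Completed years of age on ``on`` (birthday that day counts as attained)."""
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))
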