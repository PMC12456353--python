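"""Domain records for the immunization registry and generic CSV (de)serialization.

Three linked input tables arrive pre-linked on ``person_id``:

* ``persons.csv``      — person_id, birth_date, censor_date, sex
* ``enrollments.csv``  — person_id, school_year, grade, school_id, exclusion_flags
* ``doses.csv``        — person_id, antigen_group, product_code, administration_date

Dates are ISO-8601 (``YYYY-MM-DD``); month keys are ``YYYY-MM``;
``exclusion_flags`` is a semicolon-separated (possibly empty) list.

Every result record type in the package declares a ``KEY`` class attribute
naming its natural-key fields; :func:`write_table` sorts rows by that key so
that output files are deterministic, and :func:`read_table` reverses the
encoding exactly (bit-for-bit for integers, 10 significant digits for reals).
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import logging
import types
import typing
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .dates import parse_school_year
from .errors import IntegrityError, RowError, SchemaError

log = logging.getLogger(__name__)

#: Known enrollment exclusion flags, in the fixed precedence order used when
#: tallying exclusions (first matching flag names the reason).
FLAG_ORDER: tuple[str, ...] = (
    "online_only",
    "postsecondary_or_continuing",
    "summer_or_evening",
    "on_reserve",
    "lloydminster",
)

#: Antigen groups tracked by the default provincial series registry.
DEFAULT_ANTIGEN_GROUPS: frozenset[str] = frozenset(
    {"measles_containing", "pertussis_containing", "hpv", "hepatitis_b", "men_acyw"}
)

VALID_GRADES: frozenset[int] = frozenset({1, 5, 6, 9})


@dataclasses.dataclass(frozen=True)
class PersonRecord:
    person_id: str
    birth_date: dt.date
    censor_date: Optional[dt.date]  # death or out-migration; None = observed to end
    sex: str

    KEY = ("person_id",)


@dataclasses.dataclass(frozen=True)
class EnrollmentRecord:
    person_id: str
    school_year: str
    grade: int
    school_id: str
    exclusion_flags: frozenset[str]

    KEY = ("school_year", "grade", "person_id")


@dataclasses.dataclass(frozen=True)
class DoseRecord:
    """One administered, publicly funded vaccine dose."""

    person_id: str
    antigen_group: str
    product_code: str
    administration_date: dt.date

    KEY = ("person_id", "antigen_group", "administration_date", "product_code")


@dataclasses.dataclass(frozen=True)
class SeriesSpec:
    """A vaccine series tracked for one program grade.

    ``required_doses_by_cohort_year`` maps school-year labels to the dose count
    that defines *complete* coverage for that cohort year (e.g. the 3-dose HPV
    program for the 2017-2018 cohort vs 2 doses afterwards); the ``"default"``
    key covers unlisted years.
    """

    antigen_group: str
    grade: int
    required_doses_by_cohort_year: Mapping[str, int]
    dose_threshold_mode: str = "complete"  # or "at_least_one"
    label: str = ""  # display name, e.g. "DTaP-IPV"
    #: minimum days between counted doses; 0 (default) counts doses as
    #: recorded, with no inter-dose validity rule
    min_interval_days: int = 0

    def __post_init__(self) -> None:
        if not self.required_doses_by_cohort_year:
            raise SchemaError("SeriesSpec requires at least a 'default' dose count")
        for year, k in self.required_doses_by_cohort_year.items():
            if k < 1:
                raise SchemaError(f"required dose count for {year!r} must be >= 1")
        if self.dose_threshold_mode not in ("complete", "at_least_one"):
            raise SchemaError(
                f"unknown dose_threshold_mode {self.dose_threshold_mode!r}"
            )
        if self.min_interval_days < 0:
            raise SchemaError("min_interval_days must be >= 0")

    def required_doses(self, school_year: str) -> int:
        """Complete-series dose count for a cohort year."""
        table = self.required_doses_by_cohort_year
        if school_year in table:
            return table[school_year]
        if "default" in table:
            return table["default"]
        raise SchemaError(
            f"no dose requirement for cohort year {school_year!r} "
            f"({self.antigen_group}, grade {self.grade})"
        )

    def dose_threshold(self, school_year: str) -> int:
        """Counting threshold: full series, or 1 in at_least_one mode."""
        if self.dose_threshold_mode == "at_least_one":
            return 1
        return self.required_doses(school_year)


# ---------------------------------------------------------------------------
# Generic dataclass <-> CSV serialization


def _cell(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, frozenset):
        return ";".join(sorted(value))
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def _parse_cell(text: str, typ: object, where: str) -> object:
    origin = typing.get_origin(typ)
    if origin in (typing.Union, types.UnionType):
        args = [a for a in typing.get_args(typ) if a is not type(None)]
        if text == "":
            return None
        return _parse_cell(text, args[0], where)
    if typ is dt.date:
        try:
            return dt.date.fromisoformat(text)
        except ValueError as exc:
            raise RowError(f"{where}: unparseable date {text!r}") from exc
    if typ is int:
        try:
            return int(text)
        except ValueError as exc:
            raise RowError(f"{where}: not an integer: {text!r}") from exc
    if typ is float:
        try:
            return float(text)
        except ValueError as exc:
            raise RowError(f"{where}: not a number: {text!r}") from exc
    if origin is frozenset or typ is frozenset:
        return frozenset(t for t in text.split(";") if t)
    return text


def _field_types(record_type: type) -> dict[str, object]:
    return typing.get_type_hints(record_type)


def write_table(
    rows: Sequence[object], path: str | Path, record_type: type | None = None
) -> None:
    """Write a homogeneous record list as CSV, sorted by the type's natural key.

    ``record_type`` is only required for an empty list (header-only file).
    """
    if record_type is None:
        if not rows:
            raise SchemaError("record_type is required to write an empty table")
        record_type = type(rows[0])
    fields = [f.name for f in dataclasses.fields(record_type)]
    key_fields = getattr(record_type, "KEY", tuple(fields))
    ordered = sorted(rows, key=lambda r: tuple(getattr(r, k) for k in key_fields))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(fields)
        for row in ordered:
            writer.writerow([_cell(getattr(row, name)) for name in fields])


def read_table(record_type: type, path: str | Path) -> list:
    """Read a CSV written by :func:`write_table` back into records."""
    fields = dataclasses.fields(record_type)
    hints = _field_types(record_type)
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        names = [f.name for f in fields]
        missing = [n for n in names if n not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        out = []
        for i, raw in enumerate(reader, start=2):
            where = f"{path} row {i}"
            kwargs = {n: _parse_cell(raw[n], hints[n], where) for n in names}
            out.append(record_type(**kwargs))
    return out


# ---------------------------------------------------------------------------
# Registry readers with schema / row / integrity diagnostics


def _require_columns(path: Path, fieldnames: Sequence[str] | None, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in (fieldnames or [])]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_persons(path: str | Path) -> list[PersonRecord]:
    path = Path(path)
    out: list[PersonRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(path, reader.fieldnames, ["person_id", "birth_date", "censor_date", "sex"])
        for i, raw in enumerate(reader, start=2):
            where = f"{path} row {i}"
            pid = raw["person_id"].strip()
            if not pid:
                raise RowError(f"{where}: empty person_id")
            if pid in seen:
                raise IntegrityError(f"{where}: duplicate person_id {pid!r}")
            seen.add(pid)
            birth = _parse_cell(raw["birth_date"], dt.date, where)
            censor = _parse_cell(raw["censor_date"], Optional[dt.date], where)
            if censor is not None and censor < birth:
                raise RowError(f"{where}: censor_date precedes birth_date for {pid!r}")
            out.append(PersonRecord(pid, birth, censor, raw["sex"].strip()))
    return out


def read_enrollments(path: str | Path) -> list[EnrollmentRecord]:
    path = Path(path)
    out: list[EnrollmentRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(
            path, reader.fieldnames,
            ["person_id", "school_year", "grade", "school_id", "exclusion_flags"],
        )
        for i, raw in enumerate(reader, start=2):
            where = f"{path} row {i}"
            school_year = raw["school_year"].strip()
            parse_school_year(school_year)  # raises RowError if malformed
            grade = _parse_cell(raw["grade"], int, where)
            if grade not in VALID_GRADES:
                raise RowError(f"{where}: grade {grade} not in {sorted(VALID_GRADES)}")
            flags = frozenset(t for t in raw["exclusion_flags"].split(";") if t)
            unknown = flags - set(FLAG_ORDER)
            if unknown:
                raise RowError(f"{where}: unknown exclusion flag(s) {sorted(unknown)}")
            pid = raw["person_id"].strip()
            key = (pid, school_year)
            if key in seen:
                raise IntegrityError(
                    f"{where}: duplicate enrollment for person {pid!r} in {school_year}"
                )
            seen.add(key)
            out.append(EnrollmentRecord(pid, school_year, grade, raw["school_id"].strip(), flags))
    return out


def read_doses(path: str | Path, known_antigens: Iterable[str] | None = None) -> list[DoseRecord]:
    path = Path(path)
    known = frozenset(known_antigens) if known_antigens is not None else DEFAULT_ANTIGEN_GROUPS
    out: list[DoseRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(
            path, reader.fieldnames,
            ["person_id", "antigen_group", "product_code", "administration_date"],
        )
        for i, raw in enumerate(reader, start=2):
            where = f"{path} row {i}"
            antigen = raw["antigen_group"].strip()
            if antigen not in known:
                raise RowError(f"{where}: antigen_group {antigen!r} not in series registry")
            date = _parse_cell(raw["administration_date"], dt.date, where)
            out.append(DoseRecord(raw["person_id"].strip(), antigen, raw["product_code"].strip(), date))
    return out


def dedupe_doses(doses: Sequence[DoseRecord]) -> list[DoseRecord]:
    """Collapse same-day duplicates (person, antigen, date) to a single dose.

    Same-day repeats cannot be distinct valid doses of one series; one row is
    kept (lowest product_code for determinism) and a warning is logged.
    """
    by_key: dict[tuple[str, str, dt.date], DoseRecord] = {}
    dropped = 0
    for d in sorted(doses, key=lambda d: (d.person_id, d.antigen_group, d.administration_date, d.product_code)):
        key = (d.person_id, d.antigen_group, d.administration_date)
        if key in by_key:
            dropped += 1
        else:
            by_key[key] = d
    if dropped:
        log.warning("collapsed %d same-day duplicate dose row(s)", dropped)
    return list(by_key.values())


def read_registry(
    person_path: str | Path,
    enrollment_path: str | Path,
    dose_path: str | Path,
    known_antigens: Iterable[str] | None = None,
) -> tuple[list[PersonRecord], list[EnrollmentRecord], list[DoseRecord]]:
    """Read and cross-validate the three linked registry tables.

    After a successful read no dangling ``person_id`` exists, duplicate
    same-day doses have been collapsed, and every dose postdates its person's
    birth.
    """
    persons = read_persons(person_path)
    enrollments = read_enrollments(enrollment_path)
    doses = read_doses(dose_path, known_antigens)

    ids = {p.person_id for p in persons}
    bad = [(i, e.person_id) for i, e in enumerate(enrollments, start=2) if e.person_id not in ids]
    if bad:
        listing = ", ".join(f"row {i} ({pid})" for i, pid in bad[:20])
        raise IntegrityError(f"{enrollment_path}: unresolvable person_id in {listing}")
    bad = [(i, d.person_id) for i, d in enumerate(doses, start=2) if d.person_id not in ids]
    if bad:
        listing = ", ".join(f"row {i} ({pid})" for i, pid in bad[:20])
        raise IntegrityError(f"{dose_path}: unresolvable person_id in {listing}")

    birth = {p.person_id: p.birth_date for p in persons}
    early = [(i, d) for i, d in enumerate(doses, start=2) if d.administration_date < birth[d.person_id]]
    if early:
        listing = ", ".join(f"row {i} ({d.person_id})" for i, d in early[:20])
        raise IntegrityError(f"{dose_path}: administration before birth in {listing}")

    return persons, enrollments, dedupe_doses(doses)
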