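"""Cohort I/O, chronological age, age grouping and record filters.

A cohort is a CSV with one row per child: identifier, sex (M/F), ISO-8601
dates of birth (dob) and of the radiograph (dor), and per-tooth stage codes
for FDI teeth 31..37 (columns ``t31``..``t37``) with optional right-side
columns ``t41``..``t47`` used for contralateral substitution.

Chronological age (CA) is the exact day difference divided by 365.25,
recorded in years to two decimal places.  Children are grouped into yearly
exclusive class intervals [k, k+1) for k = 3..10.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Sequence

from .errors import InvalidRecordError, OutOfRangeError, ValidationError
from .staging import LEFT_MANDIBULAR_TEETH, RIGHT_MANDIBULAR_TEETH, Stage

#: Mean Julian-year length used to convert a day count to decimal years.
DAYS_PER_YEAR = 365.25

_VALID_TEETH = frozenset(LEFT_MANDIBULAR_TEETH) | frozenset(RIGHT_MANDIBULAR_TEETH)
_STAGE_COLUMNS = tuple(f"t{t}" for t in LEFT_MANDIBULAR_TEETH + RIGHT_MANDIBULAR_TEETH)
COHORT_COLUMNS = ("child_id", "sex", "dob", "dor") + _STAGE_COLUMNS


@dataclass(frozen=True, order=True)
class AgeGroup:
    """Yearly age bin [lower, lower+1), lower in 3..10."""

    lower: int

    def __post_init__(self):
        if not 3 <= self.lower <= 10:
            raise OutOfRangeError(f"age-group lower bound {self.lower} outside 3..10")

    @property
    def upper(self) -> int:
        return self.lower + 1

    @property
    def label(self) -> str:
        return f"{self.lower} to <{self.upper}"

    def __contains__(self, ca: float) -> bool:
        return self.lower <= ca < self.upper


#: The eight study groups, youngest first.
AGE_GROUPS: tuple[AgeGroup, ...] = tuple(AgeGroup(k) for k in range(3, 11))


def compute_chronological_age(
    dob: dt.date,
    dor: dt.date,
    *,
    decimals: int = 2,
    rounding: str = "half-up",
) -> float:
    """Decimal-years age at the radiograph date, rounded to ``decimals`` places.

    The convention is (exact day difference)/365.25 rounded half-up; pass
    ``rounding="half-even"`` for banker's rounding.
    """
    if dor < dob:
        raise InvalidRecordError(f"radiograph date {dor} precedes birth date {dob}")
    days = (dor - dob).days
    mode = {"half-up": ROUND_HALF_UP, "half-even": ROUND_HALF_EVEN}[rounding]
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(days) / Decimal("365.25")).quantize(q, rounding=mode))


def assign_age_group(ca: float) -> AgeGroup:
    """The yearly group with lower <= ca < upper (lower-closed, upper-open)."""
    if not 3.0 <= ca < 11.0:
        raise OutOfRangeError(f"chronological age {ca} outside the studied range [3, 11)")
    return AGE_GROUPS[int(ca) - 3]


@dataclass
class ChildRecord:
    """One subject: identity, sex, dates, per-tooth stages and derived values.

    ``stages`` maps FDI codes (31..37, 41..47) to :class:`~dentalage.staging.Stage`;
    an absent key means the tooth is missing or unreadable.  ``ca`` is derived
    from the dates at construction; ``dms`` and ``eda`` are filled in by the
    scoring/estimation steps.
    """

    child_id: str
    sex: str
    dob: dt.date
    dor: dt.date
    stages: dict[int, Stage] = field(default_factory=dict)
    ca: float | None = None
    dms: float | None = None
    eda: float | None = None

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise InvalidRecordError(f"child {self.child_id!r}: unknown sex code {self.sex!r}")
        if self.dor < self.dob:
            raise InvalidRecordError(
                f"child {self.child_id!r}: radiograph date {self.dor} precedes birth {self.dob}"
            )
        bad = set(self.stages) - _VALID_TEETH
        if bad:
            raise InvalidRecordError(
                f"child {self.child_id!r}: stage keys {sorted(bad)} not mandibular FDI codes"
            )
        if self.ca is None:
            self.ca = compute_chronological_age(self.dob, self.dor)


def _parse_row(row, rownum, problems):
    fields = {}
    child_id = (row.get("child_id") or "").strip()
    if not child_id:
        problems.append((rownum, "child_id", "empty identifier"))
    sex = (row.get("sex") or "").strip().upper()
    if sex not in ("M", "F"):
        problems.append((rownum, "sex", f"unknown sex code {row.get('sex')!r}"))
    for col in ("dob", "dor"):
        try:
            fields[col] = dt.date.fromisoformat((row.get(col) or "").strip())
        except ValueError:
            problems.append((rownum, col, f"unparseable ISO date {row.get(col)!r}"))
    stages = {}
    for col in _STAGE_COLUMNS:
        raw = (row.get(col) or "").strip()
        if not raw:
            continue
        try:
            stages[int(col[1:])] = Stage.from_code(raw)
        except ValueError:
            problems.append((rownum, col, f"unknown stage code {raw!r}"))
    if len(problems) == 0 or problems[-1][0] != rownum:
        try:
            return ChildRecord(child_id, sex, fields["dob"], fields["dor"], stages)
        except InvalidRecordError as exc:
            problems.append((rownum, "dor", str(exc)))
    return None


def read_cohort_lenient(path) -> tuple[list[ChildRecord], list[tuple[int, str, str]]]:
    """Parse a cohort CSV, collecting malformed rows instead of raising.

    Returns ``(records, problems)`` where each problem is
    ``(row_number, column, message)``.
    """
    records, problems = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"child_id", "sex", "dob", "dor"} <= set(
            reader.fieldnames
        ):
            raise ValidationError([(1, "header", "missing required columns child_id/sex/dob/dor")])
        for rownum, row in enumerate(reader, start=2):
            rec = _parse_row(row, rownum, problems)
            if rec is not None:
                records.append(rec)
    return records, problems


def read_cohort(path) -> list[ChildRecord]:
    """Strictly parse a cohort CSV; any malformed cell raises ValidationError."""
    records, problems = read_cohort_lenient(path)
    if problems:
        raise ValidationError(problems)
    return records


def write_cohort(records: Iterable[ChildRecord], path) -> None:
    """Write records as a cohort CSV (round-trips through :func:`read_cohort`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            row = [r.child_id, r.sex, r.dob.isoformat(), r.dor.isoformat()]
            row += [
                r.stages[t].code if t in r.stages else ""
                for t in LEFT_MANDIBULAR_TEETH + RIGHT_MANDIBULAR_TEETH
            ]
            writer.writerow(row)


class Exclusion(NamedTuple):
    """One exclusion-log entry."""

    child_id: str
    reason: str
    value: float


class FilterResult(NamedTuple):
    retained: list[ChildRecord]
    excluded: list[ChildRecord]
    log: list[Exclusion]


def exclude_below_min_age(
    records: Sequence[ChildRecord], min_eda: float = 2.5
) -> FilterResult:
    """Drop records whose estimated dental age falls below ``min_eda`` years.

    Mirrors the study-range exclusion applied after radiograph interpretation.
    Every record must already carry an ``eda``; retained and excluded always
    partition the input, and each removal is logged.
    """
    retained, excluded, log = [], [], []
    for r in records:
        if r.eda is None:
            raise InvalidRecordError(f"child {r.child_id!r}: eda not set before age filter")
        if r.eda < min_eda:
            excluded.append(r)
            log.append(Exclusion(r.child_id, f"eda below {min_eda}", r.eda))
        else:
            retained.append(r)
    return FilterResult(retained, excluded, log)


def write_exclusion_log(log: Iterable[Exclusion], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("child_id", "reason", "value"))
        writer.writerows(log)
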