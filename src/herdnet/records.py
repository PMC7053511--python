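"""Domain types and tabular I/O for herd rosters and focal-sampling records.

A focal-sampling campaign observes every animal of a herd once per
observation period, recording the single activity it performs and the set
of conspecifics it is in proximity with (same activity, within the
proximity criterion).  This module defines the validated in-memory model
(:class:`Animal`, :class:`ObservationRecord`, :class:`ObservationPeriod`)
and CSV readers/writers for the roster and the observation records.

Validation enforces the observational protocol: one record per
(animal, period), a closed activity catalogue, same-activity proximity,
and symmetric partner sets (proximity is a reciprocal relation; when only
one side of a pair was recorded the reader symmetrizes by union and logs
a warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The closed catalogue of activities, in canonical order.
ACTIVITIES: tuple[str, ...] = (
    "grazing",
    "moving",
    "standing",
    "ruminating",
    "wallowing",
    "lying",
    "drinking",
)

FEMALE = 1
MALE = 2

_GENDER_CODES: dict[object, int] = {
    1: FEMALE,
    2: MALE,
    "1": FEMALE,
    "2": MALE,
    "female": FEMALE,
    "male": MALE,
    "f": FEMALE,
    "m": MALE,
}


class ValidationError(ValueError):
    """Raised when a roster or records table violates the protocol."""


@dataclass(frozen=True)
class Animal:
    """One roster entry: identity, age in years, gender (1=female, 2=male)."""

    animal_id: str
    age: float
    gender: int

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise ValidationError("animal_id must be a non-empty string")
        if not self.age > 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: age must be positive, got {self.age}"
            )
        if self.gender not in (FEMALE, MALE):
            raise ValidationError(
                f"animal {self.animal_id!r}: gender must be 1 (female) or 2 (male), "
                f"got {self.gender!r}"
            )


@dataclass(frozen=True)
class ObservationPeriod:
    """One 30-minute observation step.

    The default campaign design is 12 months x 2 session days x 10 steps
    (5 observation hours, 2 steps per hour) = 240 periods; ``period_id``
    is the ordinal 1..P bijective with (month, session, time_step).
    """

    period_id: int
    month: int
    session: int
    time_step: int

    def __post_init__(self) -> None:
        if self.period_id < 1:
            raise ValidationError(f"period_id must be >= 1, got {self.period_id}")
        if not (1 <= self.session <= 2 and 1 <= self.time_step <= 10 and self.month >= 1):
            raise ValidationError(
                f"period {self.period_id}: invalid (month={self.month}, "
                f"session={self.session}, time_step={self.time_step})"
            )
        expected = period_from_id(self.period_id)
        if (expected.month, expected.session, expected.time_step) != (
            self.month,
            self.session,
            self.time_step,
        ):
            raise ValidationError(
                f"period {self.period_id}: (month, session, time_step)="
                f"({self.month}, {self.session}, {self.time_step}) does not match "
                f"the ordinal design position"
            )


def period_from_id(period_id: int) -> ObservationPeriod:
    """Map an ordinal period id to its (month, session, time_step) position.

    Sessions of 10 half-hour steps, two sessions per month.
    """
    i = period_id - 1
    obj = object.__new__(ObservationPeriod)
    object.__setattr__(obj, "period_id", period_id)
    object.__setattr__(obj, "month", i // 20 + 1)
    object.__setattr__(obj, "session", (i % 20) // 10 + 1)
    object.__setattr__(obj, "time_step", i % 10 + 1)
    return obj


def design_periods(n_periods: int = 240) -> list[ObservationPeriod]:
    """The campaign design as an ordered list of periods (default 240)."""
    return [period_from_id(p) for p in range(1, n_periods + 1)]


@dataclass(frozen=True)
class ObservationRecord:
    """One animal's activity and proximity partners in one period.

    ``partners`` may be empty (the animal was alone in its activity).
    """

    period_id: int
    animal_id: str
    activity: str
    partners: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValidationError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )
        if self.animal_id in self.partners:
            raise ValidationError(
                f"animal {self.animal_id!r} (period {self.period_id}): "
                "an animal cannot be its own proximity partner"
            )


def _coerce_gender(value: object, animal_id: str) -> int:
    key = value
    if isinstance(value, str):
        key = value.strip().lower()
    elif isinstance(value, float) and value == int(value):
        key = int(value)
    try:
        return _GENDER_CODES[key]
    except KeyError:
        raise ValidationError(
            f"animal {animal_id!r}: unrecognized gender {value!r} "
            "(accepted: 1, 2, 'female', 'male')"
        ) from None


# ---------------------------------------------------------------------------
# Roster I/O


def read_roster(path: str | Path) -> list[Animal]:
    """Read and validate a roster CSV with columns animal_id, age, gender.

    Gender may be coded 1/2 or spelled "female"/"male"; it is returned as
    the numeric code (1=female, 2=male).  Duplicate ids and non-positive
    ages raise :class:`ValidationError` naming the offending animal.
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    missing = {"animal_id", "age", "gender"} - set(df.columns)
    if missing:
        raise ValidationError(f"roster {path}: missing columns {sorted(missing)}")
    dupes = df["animal_id"][df["animal_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"roster {path}: duplicate animal ids {dupes}")
    return [
        Animal(
            animal_id=row.animal_id,
            age=float(row.age),
            gender=_coerce_gender(row.gender, row.animal_id),
        )
        for row in df.itertuples()
    ]


def write_roster(roster: Sequence[Animal], path: str | Path) -> None:
    pd.DataFrame(
        {
            "animal_id": [a.animal_id for a in roster],
            "age": [a.age for a in roster],
            "gender": [a.gender for a in roster],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Records I/O


def _symmetrize(
    records: dict[tuple[int, str], ObservationRecord]
) -> dict[tuple[int, str], ObservationRecord]:
    """Close partner sets under reciprocity within each period.

    Proximity is a mutual event; if A lists B but B omits A, B's set gains
    A (union closure) and a warning is logged.  Idempotent.  Proximity is
    not transitively closed: only recorded pairs become edges.
    """
    closed = dict(records)
    for (period_id, animal_id), rec in records.items():
        for partner in rec.partners:
            other = closed[(period_id, partner)]
            if animal_id not in other.partners:
                logger.warning(
                    "period %s: %s listed %s but not vice versa; symmetrizing",
                    period_id,
                    animal_id,
                    partner,
                )
                closed[(period_id, partner)] = replace(
                    other, partners=other.partners | {animal_id}
                )
    return closed


def validate_records(
    records: Iterable[ObservationRecord],
    roster: Sequence[Animal],
    *,
    symmetrize: bool = True,
) -> list[ObservationRecord]:
    """Validate (and by default symmetrize) a collection of records.

    Enforces: known animals, one record per (animal, period), partners on
    the roster and observed performing the same activity in the same
    period.  Returns records sorted by (period, roster order).
    """
    ids = [a.animal_id for a in roster]
    known = set(ids)
    by_key: dict[tuple[int, str], ObservationRecord] = {}
    for rec in records:
        if rec.animal_id not in known:
            raise ValidationError(f"record references unknown animal {rec.animal_id!r}")
        key = (rec.period_id, rec.animal_id)
        if key in by_key:
            raise ValidationError(
                f"animal {rec.animal_id!r} has two records in period {rec.period_id}: "
                "activities are mutually exclusive, one observation per period"
            )
        by_key[key] = rec
    for (period_id, animal_id), rec in by_key.items():
        for partner in rec.partners:
            if partner not in known:
                raise ValidationError(
                    f"period {period_id}: {animal_id!r} lists unknown partner {partner!r}"
                )
            mate = by_key.get((period_id, partner))
            if mate is None:
                raise ValidationError(
                    f"period {period_id}: {animal_id!r} lists partner {partner!r} "
                    "which has no record in that period"
                )
            if mate.activity != rec.activity:
                raise ValidationError(
                    f"period {period_id}: {animal_id!r} ({rec.activity}) in proximity "
                    f"with {partner!r} ({mate.activity}); proximity requires the "
                    "same activity"
                )
    if symmetrize:
        by_key = _symmetrize(by_key)
    order = {a: i for i, a in enumerate(ids)}
    return sorted(by_key.values(), key=lambda r: (r.period_id, order[r.animal_id]))


def read_records(path: str | Path, roster: Sequence[Animal]) -> list[ObservationRecord]:
    """Read focal-sampling records from CSV and validate against the roster.

    Expected columns: period_id, month, session, time_step, animal_id,
    activity, partners (semicolon-joined ids; empty = no partners).
    Errors cite the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "partners": str}, keep_default_na=False)
    required = {"period_id", "animal_id", "activity", "partners"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"records {path}: missing columns {sorted(missing)}")
    known = {a.animal_id for a in roster}
    records: list[ObservationRecord] = []
    for rownum, row in enumerate(df.itertuples(), start=1):
        if row.animal_id not in known:
            raise ValidationError(
                f"records {path} row {rownum}: unknown animal {row.animal_id!r}"
            )
        if row.activity not in ACTIVITIES:
            raise ValidationError(
                f"records {path} row {rownum}: unknown activity {row.activity!r}"
            )
        period_id = int(row.period_id)
        if {"month", "session", "time_step"} <= set(df.columns):
            # Consistency of the ordinal id with its stated design position.
            ObservationPeriod(
                period_id=period_id,
                month=int(row.month),
                session=int(row.session),
                time_step=int(row.time_step),
            )
        partners = frozenset(p for p in str(row.partners).split(";") if p)
        try:
            records.append(
                ObservationRecord(
                    period_id=period_id,
                    animal_id=row.animal_id,
                    activity=row.activity,
                    partners=partners,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"records {path} row {rownum}: {exc}") from None
    return validate_records(records, roster)


def write_records(records: Sequence[ObservationRecord], path: str | Path) -> None:
    """Write records to CSV; round-trips exactly through :func:`read_records`.

    The (month, session, time_step) columns are derived from period_id via
    the campaign design layout.
    """
    rows = []
    for rec in records:
        per = period_from_id(rec.period_id)
        rows.append(
            {
                "period_id": rec.period_id,
                "month": per.month,
                "session": per.session,
                "time_step": per.time_step,
                "animal_id": rec.animal_id,
                "activity": rec.activity,
                "partners": ";".join(sorted(rec.partners)),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "period_id",
            "month",
            "session",
            "time_step",
            "animal_id",
            "activity",
            "partners",
        ],
    ).to_csv(path, index=False)


def roster_dataframe(roster: Sequence[Animal]) -> pd.DataFrame:
    """Roster as a DataFrame indexed by animal_id (age, gender columns)."""
    return pd.DataFrame(
        {
            "animal_id": [a.animal_id for a in roster],
            "age": [a.age for a in roster],
            "gender": [a.gender for a in roster],
        }
    ).set_index("animal_id")
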