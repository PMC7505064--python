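"""Capture-record data model and I/O.

A :class:`BearRecord` is one capture, control-kill or harvest event for one
bear: body mass (kg), straight-line body length (cm), optional torso height
(cm), age (exact years, or a plausible range when cementum reading failed),
sex and date. Records are the unit of the allometric body-condition analysis
and of growth-curve fitting.

Season and age class are derived attributes. The sampling window runs April
through November (bears den December–March); the three seasons track the
major diet shifts of Hokkaido brown bears. Age classes use sex-specific
thresholds derived from the age at which each sex reaches 95 % of asymptotic
body length: females are adult from 5 years, males from 8.
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Sex",
    "Season",
    "AgeClass",
    "Source",
    "BearRecord",
    "DenningSeasonError",
    "SchemaError",
    "assign_season",
    "assign_age_class",
    "dedupe_repeats",
    "read_bear_records",
    "write_bear_records",
    "records_to_frame",
]


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Season(str, Enum):
    """Diet-based field seasons (denning months Dec–Mar are out of window)."""

    SPRING = "spring"  # April–June: mainly grasses
    SUMMER = "summer"  # July–August: grasses and ants
    AUTUMN = "autumn"  # September–November: berries and acorns


class AgeClass(str, Enum):
    CUB = "cub"
    SUBADULT = "subadult"
    ADULT = "adult"


class Source(str, Enum):
    RESEARCH_CAPTURE = "research_capture"
    CONTROL_KILL = "control_kill"
    HARVEST = "harvest"


class DenningSeasonError(ValueError):
    """Raised for dates outside the April–November sampling window."""


class SchemaError(ValueError):
    """Raised when a records CSV is missing required columns."""


# CSV schema (UTF-8, header required)
CSV_COLUMNS = (
    "bear_id",
    "sex",
    "age_years",
    "age_min",
    "age_max",
    "date",
    "body_mass_kg",
    "body_length_cm",
    "torso_height_cm",
    "source",
)
_REQUIRED_COLUMNS = (
    "bear_id",
    "sex",
    "date",
    "body_mass_kg",
    "body_length_cm",
)

# Sex-specific age-class thresholds (years). Age 0 is a cub; age 1 starts the
# subadult class (the class definitions are disjoint under this reading).
_ADULT_FROM = {Sex.FEMALE: 5, Sex.MALE: 8}


@dataclass(frozen=True)
class BearRecord:
    """One morphometric measurement event for one bear.

    Invariants are enforced at construction: mass and length strictly
    positive, torso height (when present) positive and smaller than body
    length, and exact age and age range mutually exclusive.
    """

    bear_id: str
    sex: Sex
    date: dt.date
    body_mass: float  # kg
    body_length: float  # cm
    age_years: int | None = None
    age_range: tuple[int, int] | None = None
    torso_height: float | None = None  # cm
    source: Source = Source.CONTROL_KILL

    def __post_init__(self) -> None:
        if not self.body_mass > 0:
            raise ValueError(f"body_mass must be > 0, got {self.body_mass}")
        if not self.body_length > 0:
            raise ValueError(f"body_length must be > 0, got {self.body_length}")
        if self.torso_height is not None:
            if not self.torso_height > 0:
                raise ValueError("torso_height must be > 0 when present")
            if self.torso_height >= self.body_length:
                raise ValueError(
                    "torso_height must be smaller than body_length "
                    f"({self.torso_height} >= {self.body_length})"
                )
        if self.age_years is not None:
            if self.age_years < 0:
                raise ValueError("age_years must be nonnegative")
            if self.age_range is not None:
                raise ValueError("age_years and age_range are mutually exclusive")
        if self.age_range is not None:
            lo, hi = self.age_range
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid age_range {self.age_range}")

    @property
    def season(self) -> Season:
        return assign_season(self.date)

    @property
    def age_class(self) -> AgeClass | None:
        """Age class, or None when the record cannot be classified."""
        try:
            return assign_age_class(
                self.sex, age_years=self.age_years, age_range=self.age_range
            )
        except ValueError:
            return None

    @property
    def best_age(self) -> float:
        """Age used for ordering repeated captures (midpoint of a range)."""
        if self.age_years is not None:
            return float(self.age_years)
        if self.age_range is not None:
            return (self.age_range[0] + self.age_range[1]) / 2.0
        return float("-inf")


def assign_season(date: dt.date) -> Season:
    """Map a sampling date to its diet season by calendar month.

    April–June -> spring, July–August -> summer, September–November ->
    autumn. December–March raise :class:`DenningSeasonError`.
    """
    m = date.month
    if 4 <= m <= 6:
        return Season.SPRING
    if m in (7, 8):
        return Season.SUMMER
    if 9 <= m <= 11:
        return Season.AUTUMN
    raise DenningSeasonError(
        f"month {m} is in the denning season (outside April–November)"
    )


def assign_age_class(
    sex: Sex,
    age_years: int | None = None,
    age_range: tuple[int, int] | None = None,
) -> AgeClass:
    """Assign cub / subadult / adult with sex-specific thresholds.

    Females: 0 cub, 1–4 subadult, >=5 adult. Males: 0 cub, 1–7 subadult,
    >=8 adult. An age range is accepted only if it lies entirely within one
    class; a straddling range raises ValueError (such records are excluded
    from class-stratified analyses).
    """
    sex = Sex(sex)
    adult_from = _ADULT_FROM[sex]

    def classify(a: int) -> AgeClass:
        if a == 0:
            return AgeClass.CUB
        if a < adult_from:
            return AgeClass.SUBADULT
        return AgeClass.ADULT

    if age_years is not None:
        if age_years < 0:
            raise ValueError("age must be nonnegative")
        return classify(int(age_years))
    if age_range is not None:
        lo, hi = int(age_range[0]), int(age_range[1])
        c_lo, c_hi = classify(lo), classify(hi)
        if c_lo != c_hi:
            raise ValueError(
                f"age range {age_range} straddles classes {c_lo.value}/{c_hi.value}"
            )
        return c_lo
    raise ValueError("either age_years or age_range is required")


def dedupe_repeats(records: Sequence[BearRecord]) -> list[BearRecord]:
    """Keep one record per bear: the measurement taken at the greatest age.

    Ties on age keep the later date (more recent body state). Singletons pass
    through unchanged; the operation is idempotent and order-preserving with
    respect to each kept record's first appearance.
    """
    best: dict[str, BearRecord] = {}
    order: list[str] = []
    for rec in records:
        prev = best.get(rec.bear_id)
        if prev is None:
            best[rec.bear_id] = rec
            order.append(rec.bear_id)
        elif (rec.best_age, rec.date) > (prev.best_age, prev.date):
            best[rec.bear_id] = rec
    return [best[bid] for bid in order]


def _parse_row(row: dict[str, str], lineno: int) -> BearRecord:
    def opt_float(key: str) -> float | None:
        v = (row.get(key) or "").strip()
        return float(v) if v else None

    def opt_int(key: str) -> int | None:
        v = (row.get(key) or "").strip()
        return int(float(v)) if v else None

    mass = opt_float("body_mass_kg")
    length = opt_float("body_length_cm")
    if mass is None or length is None:
        raise ValueError(f"row {lineno}: body_mass_kg and body_length_cm required")
    age_min, age_max = opt_int("age_min"), opt_int("age_max")
    age_range = (age_min, age_max) if age_min is not None and age_max is not None else None
    source_raw = (row.get("source") or "").strip()
    return BearRecord(
        bear_id=row["bear_id"].strip(),
        sex=Sex(row["sex"].strip().lower()),
        date=dt.date.fromisoformat(row["date"].strip()),
        body_mass=mass,
        body_length=length,
        age_years=opt_int("age_years"),
        age_range=age_range,
        torso_height=opt_float("torso_height_cm"),
        source=Source(source_raw) if source_raw else Source.CONTROL_KILL,
    )


def read_bear_records(path: str | Path) -> list[BearRecord]:
    """Read capture records from CSV, rejecting invalid rows with a warning.

    Raises :class:`SchemaError` when a required column is absent. Rows whose
    values violate record invariants (for example a nonpositive mass) are
    skipped; one warning per rejected row carries the row number and reason.
    """
    path = Path(path)
    records: list[BearRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, lineno))
            except (ValueError, KeyError) as exc:
                warnings.warn(
                    f"{path.name} row {lineno} rejected: {exc}", stacklevel=2
                )
    return records


def write_bear_records(records: Iterable[BearRecord], path: str | Path) -> None:
    """Write records as CSV in the documented schema (round-trips losslessly)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            age_min, age_max = r.age_range if r.age_range else ("", "")
            writer.writerow(
                [
                    r.bear_id,
                    r.sex.value,
                    "" if r.age_years is None else r.age_years,
                    age_min,
                    age_max,
                    r.date.isoformat(),
                    repr(float(r.body_mass)),
                    repr(float(r.body_length)),
                    "" if r.torso_height is None else repr(float(r.torso_height)),
                    r.source.value,
                ]
            )


def records_to_frame(records: Sequence[BearRecord]):
    """Tabulate records as a pandas DataFrame with derived season/age class."""
    import pandas as pd

    rows = []
    for r in records:
        ac = r.age_class
        rows.append(
            {
                "bear_id": r.bear_id,
                "sex": r.sex.value,
                "age_years": r.age_years,
                "date": r.date,
                "body_mass_kg": r.body_mass,
                "body_length_cm": r.body_length,
                "torso_height_cm": r.torso_height,
                "source": r.source.value,
                "season": r.season.value,
                "age_class": None if ac is None else ac.value,
            }
        )
    return pd.DataFrame(rows)
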