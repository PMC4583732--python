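"""Traveler-level survey data model: CSV ingestion and validation, ICD-10
chapter assignment, and the categorical collapsing applied before analysis.

The unit of observation is one medical traveler (one household). Money is
held as integer cents (see :mod:`mtoburden._money`); the CSV interface is
USD with two decimals.
"""
from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from ._money import format_usd, to_cents

STRATA = ("subsidized", "private")
SEXES = ("female", "male")
REGIONS = ("North", "Central", "South")
OCCUPATIONS = ("civil_servant", "private_sector", "own_business", "not_employed", "other")

#: Cost components of one overseas treatment episode. Only direct medical
#: care and the airfare can carry a government subsidy; everything else is
#: out-of-pocket by construction of the benefit package.
COMPONENTS = (
    "direct_medical",
    "travel_home",
    "airfare",
    "travel_destination",
    "entertainment",
    "lodging",
    "food",
    "visa",
    "foreign_exchange",
    "other",
)
SUBSIDIZABLE = ("direct_medical", "airfare")

#: Cost components that together form "travel" in summary tables.
TRAVEL_COMPONENTS = ("travel_home", "airfare", "travel_destination")

#: CSV schema, in column order. Money columns are USD with 2 decimals.
CSV_COLUMNS = (
    "id", "stratum", "sex", "age", "region", "occupation",
    "household_size", "household_income_month", "icd_code", "destination",
    "los_days", "n_caretakers", "visits_per_year",
    "cost_medical_subsidy", "cost_medical_oop", "cost_travel_home_oop",
    "cost_airfare_subsidy", "cost_airfare_oop", "cost_travel_dest_oop",
    "cost_entertainment_oop", "cost_lodging_oop", "cost_food_oop",
    "cost_visa_oop", "cost_fx_oop", "cost_other_oop",
    "prod_hours_per_day", "prod_income_per_day",
    "hh_health_month", "hh_food_month", "hh_other_month",
)

MONEY_COLUMNS = tuple(c for c in CSV_COLUMNS if c.startswith(("cost_", "hh_"))) + (
    "household_income_month", "prod_income_per_day",
)


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a record invariant."""


class ChapterError(ValueError):
    """An ICD code present but not parseable as letter+digits."""


@dataclass(frozen=True)
class CostBreakdown:
    """Itemized episode cost, integer cents per (component, payer)."""

    medical_subsidy: int = 0
    medical_oop: int = 0
    travel_home_oop: int = 0
    airfare_subsidy: int = 0
    airfare_oop: int = 0
    travel_dest_oop: int = 0
    entertainment_oop: int = 0
    lodging_oop: int = 0
    food_oop: int = 0
    visa_oop: int = 0
    fx_oop: int = 0
    other_oop: int = 0

    def component(self, name: str) -> tuple[int, int]:
        """(subsidy, oop) cents for one component."""
        m = {
            "direct_medical": (self.medical_subsidy, self.medical_oop),
            "travel_home": (0, self.travel_home_oop),
            "airfare": (self.airfare_subsidy, self.airfare_oop),
            "travel_destination": (0, self.travel_dest_oop),
            "entertainment": (0, self.entertainment_oop),
            "lodging": (0, self.lodging_oop),
            "food": (0, self.food_oop),
            "visa": (0, self.visa_oop),
            "foreign_exchange": (0, self.fx_oop),
            "other": (0, self.other_oop),
        }
        return m[name]

    def component_total(self, name: str) -> int:
        s, o = self.component(name)
        return s + o

    def subsidy_total(self) -> int:
        return self.medical_subsidy + self.airfare_subsidy

    def oop_total(self) -> int:
        return sum(self.component(c)[1] for c in COMPONENTS)

    def total(self) -> int:
        return self.subsidy_total() + self.oop_total()

    def __post_init__(self) -> None:
        for f, v in self.__dict__.items():
            if v < 0:
                raise ValidationError(f"negative cost field {f}: {v}")


@dataclass(frozen=True)
class ProductivityInput:
    """Inputs for the productivity-loss product: hours lost per day spent
    abroad, days abroad, and the traveler's daily income."""

    hours_lost_per_day: float
    days_abroad: float
    income_per_day: int  # cents

    def __post_init__(self) -> None:
        if not 0 <= self.hours_lost_per_day <= 24:
            raise ValidationError(f"hours_lost_per_day out of [0,24]: {self.hours_lost_per_day}")
        if self.days_abroad < 0 or self.income_per_day < 0:
            raise ValidationError("negative productivity input")


@dataclass(frozen=True)
class HouseholdBudget:
    """Monthly out-of-pocket household spending (cents) on health, food and
    everything else; the denominator of the catastrophic-payment share."""

    health_month: int
    food_month: int
    other_month: int

    def __post_init__(self) -> None:
        if min(self.health_month, self.food_month, self.other_month) < 0:
            raise ValidationError("negative household budget field")

    @property
    def total_month(self) -> int:
        return self.health_month + self.food_month + self.other_month


@dataclass(frozen=True)
class DiseaseChapter:
    code_start: str
    code_end: str
    label: str
    profile_eligible: bool

    @property
    def code_range(self) -> str:
        return f"{self.code_start}-{self.code_end}"


#: Sentinel for records with no diagnosis code; excluded from disease-profile
#: tables alongside the Z chapter, but never an error.
MISSING_CHAPTER = DiseaseChapter("", "", "missing", False)


@dataclass(frozen=True)
class TravelerRecord:
    id: str
    stratum: str
    sex: str
    age: int
    region: str
    occupation: str
    household_size: int
    household_income_month: int  # cents
    icd_code: str | None
    destination: str
    los_days: float
    n_caretakers: int
    visits_per_year: int
    costs: CostBreakdown
    productivity: ProductivityInput
    household_budget: HouseholdBudget

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValidationError(f"unknown stratum {self.stratum!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.occupation not in OCCUPATIONS:
            raise ValidationError(f"unknown occupation {self.occupation!r}")
        if self.age < 0:
            raise ValidationError(f"negative age: {self.age}")
        if self.household_size < 1:
            raise ValidationError(f"household_size < 1: {self.household_size}")
        if self.household_income_month < 0:
            raise ValidationError(f"negative household_income_month (id={self.id})")
        if self.los_days < 0 or self.n_caretakers < 0:
            raise ValidationError(f"negative los_days/n_caretakers (id={self.id})")
        if self.visits_per_year < 1:
            raise ValidationError(f"visits_per_year < 1 (id={self.id})")


@dataclass
class LoadResult:
    records: list[TravelerRecord]
    errors: list[tuple[str, str]] = field(default_factory=list)  # (row id, reason)
    n_rows: int = 0


# ---------------------------------------------------------------------------
# ICD-10 chapters

_ICD_RE = re.compile(r"^([A-Z])(\d{2})")


def _load_chapters() -> tuple[DiseaseChapter, ...]:
    text = resources.files("mtoburden.resources").joinpath("icd10_chapters.tsv").read_text()
    chapters = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        start, end, label, eligible = line.split("\t")
        chapters.append(DiseaseChapter(start, end, label, eligible.strip() == "1"))
    return tuple(chapters)


CHAPTERS: tuple[DiseaseChapter, ...] = _load_chapters()


def _code_key(code: str) -> tuple[str, int]:
    m = _ICD_RE.match(code.strip().upper())
    if m is None:
        raise ChapterError(f"unparseable ICD-10 code: {code!r}")
    return m.group(1), int(m.group(2))


def assign_icd_chapter(icd_code: str | None) -> DiseaseChapter:
    """Map an ICD-10 code to its major chapter.

    Missing codes (None or blank) map to the ``MISSING_CHAPTER`` sentinel.
    Codes in inter-chapter gaps (e.g. D49) fall to the preceding chapter so
    that assignment is total on the A00-Z99 letter+digit space.
    """
    if icd_code is None or not str(icd_code).strip():
        return MISSING_CHAPTER
    key = _code_key(str(icd_code))
    best = None
    for ch in CHAPTERS:
        if _code_key(ch.code_start) <= key:
            best = ch
    if best is None:
        raise ChapterError(f"code {icd_code!r} precedes the first chapter")
    return best


def filter_disease_profile(records: Sequence[TravelerRecord]) -> tuple[list[TravelerRecord], int]:
    """Keep records whose chapter enters disease-profile tables; return the
    subset and the number omitted (Z chapter plus missing codes)."""
    kept = [r for r in records if assign_icd_chapter(r.icd_code).profile_eligible]
    omitted = len(records) - len(kept)
    if records and not kept:
        warnings.warn("all records fall outside the disease profile", stacklevel=2)
    return kept, omitted


# ---------------------------------------------------------------------------
# Categorical collapsing

AGE_LABELS = ("Children <=9 yrs", "Adolescents 10-19 yrs", "Youth 20-29 yrs",
              "Adult 30-59 yrs", "Elderly >=60 yrs")
SIZE_LABELS = ("Small (<=5 members)", "Medium (6-10 members)", "Large (>10 members)")
LOS_LABELS = ("<=1 week", "2 weeks", "3 weeks", "1 month", ">1 month")


def age_group(age: int) -> str:
    if age <= 9:
        return AGE_LABELS[0]
    if age <= 19:
        return AGE_LABELS[1]
    if age <= 29:
        return AGE_LABELS[2]
    if age <= 59:
        return AGE_LABELS[3]
    return AGE_LABELS[4]


def household_size_class(size: int) -> str:
    # the small/medium boundary places size 5 in "small" so classes partition
    if size <= 5:
        return SIZE_LABELS[0]
    if size <= 10:
        return SIZE_LABELS[1]
    return SIZE_LABELS[2]


def los_class(days: float) -> str:
    """Collapse days abroad into stay classes: whole weeks by ceiling
    (week k covers 7(k-1)+1 .. 7k days), '1 month' = 22-31 days, beyond a
    month above that."""
    if days <= 7:
        return LOS_LABELS[0]
    if days <= 14:
        return LOS_LABELS[1]
    if days <= 21:
        return LOS_LABELS[2]
    if days <= 31:
        return LOS_LABELS[3]
    return LOS_LABELS[4]


def categorize(record: TravelerRecord) -> dict[str, str]:
    """Categorical labels used by the summary tables."""
    return {
        "age_group": age_group(record.age),
        "household_size_class": household_size_class(record.household_size),
        "los_class": los_class(record.los_days),
        "region": record.region,
    }


def quintiles(values: Sequence[float]) -> np.ndarray:
    """Sample-based quintile labels 1-5.

    Cut points are the sorted-sample values at the 20/40/60/80 % boundary
    positions; a value equal to a cut point takes the lower quintile, so
    binning is stable under reordering and monotone in the value.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 values for quintile binning")
    srt = np.sort(x)
    n = x.size
    cuts = [srt[int(np.ceil(k * n / 5)) - 1] for k in (1, 2, 3, 4)]
    q = np.ones(n, dtype=int)
    for c in cuts:
        q += (x > c).astype(int)
    if np.all(x == x[0]):
        warnings.warn("all incomes identical; every record in quintile 1", stacklevel=2)
    return q


def bin_income_quintiles(records: Sequence[TravelerRecord]) -> dict[str, int]:
    """Quintile (1-5) of monthly household income for each record id."""
    q = quintiles([r.household_income_month for r in records])
    return {r.id: int(qi) for r, qi in zip(records, q)}


# ---------------------------------------------------------------------------
# CSV interface


def _record_from_row(row: dict[str, str]) -> TravelerRecord:
    money = {c: to_cents(row[c]) for c in MONEY_COLUMNS}
    for c, v in money.items():
        if v < 0:
            raise ValidationError(f"negative money in column {c} (id={row['id']})")
    costs = CostBreakdown(
        medical_subsidy=money["cost_medical_subsidy"],
        medical_oop=money["cost_medical_oop"],
        travel_home_oop=money["cost_travel_home_oop"],
        airfare_subsidy=money["cost_airfare_subsidy"],
        airfare_oop=money["cost_airfare_oop"],
        travel_dest_oop=money["cost_travel_dest_oop"],
        entertainment_oop=money["cost_entertainment_oop"],
        lodging_oop=money["cost_lodging_oop"],
        food_oop=money["cost_food_oop"],
        visa_oop=money["cost_visa_oop"],
        fx_oop=money["cost_fx_oop"],
        other_oop=money["cost_other_oop"],
    )
    los = float(row["los_days"])
    prod = ProductivityInput(
        hours_lost_per_day=float(row["prod_hours_per_day"]),
        days_abroad=los,
        income_per_day=money["prod_income_per_day"],
    )
    budget = HouseholdBudget(
        health_month=money["hh_health_month"],
        food_month=money["hh_food_month"],
        other_month=money["hh_other_month"],
    )
    return TravelerRecord(
        id=row["id"],
        stratum=row["stratum"],
        sex=row["sex"],
        age=int(row["age"]),
        region=row["region"],
        occupation=row["occupation"],
        household_size=int(row["household_size"]),
        household_income_month=money["household_income_month"],
        icd_code=row["icd_code"] or None,
        destination=row["destination"],
        los_days=los,
        n_caretakers=int(row["n_caretakers"]),
        visits_per_year=int(row["visits_per_year"]),
        costs=costs,
        productivity=prod,
        household_budget=budget,
    )


def load_survey(path) -> LoadResult:
    """Read a traveler survey CSV.

    Invalid rows are collected with their reason, never silently dropped; a
    malformed header is a hard :class:`SchemaError`.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        result = LoadResult(records=[])
        for row in reader:
            result.n_rows += 1
            try:
                result.records.append(_record_from_row(row))
            except (ValidationError, ValueError) as exc:
                result.errors.append((row.get("id", f"row{result.n_rows}"), str(exc)))
    return result


def record_to_row(r: TravelerRecord) -> dict[str, str]:
    c = r.costs
    return {
        "id": r.id,
        "stratum": r.stratum,
        "sex": r.sex,
        "age": str(r.age),
        "region": r.region,
        "occupation": r.occupation,
        "household_size": str(r.household_size),
        "household_income_month": format_usd(r.household_income_month),
        "icd_code": r.icd_code or "",
        "destination": r.destination,
        "los_days": repr(r.los_days),
        "n_caretakers": str(r.n_caretakers),
        "visits_per_year": str(r.visits_per_year),
        "cost_medical_subsidy": format_usd(c.medical_subsidy),
        "cost_medical_oop": format_usd(c.medical_oop),
        "cost_travel_home_oop": format_usd(c.travel_home_oop),
        "cost_airfare_subsidy": format_usd(c.airfare_subsidy),
        "cost_airfare_oop": format_usd(c.airfare_oop),
        "cost_travel_dest_oop": format_usd(c.travel_dest_oop),
        "cost_entertainment_oop": format_usd(c.entertainment_oop),
        "cost_lodging_oop": format_usd(c.lodging_oop),
        "cost_food_oop": format_usd(c.food_oop),
        "cost_visa_oop": format_usd(c.visa_oop),
        "cost_fx_oop": format_usd(c.fx_oop),
        "cost_other_oop": format_usd(c.other_oop),
        "prod_hours_per_day": repr(r.productivity.hours_lost_per_day),
        "prod_income_per_day": format_usd(r.productivity.income_per_day),
        "hh_health_month": format_usd(r.household_budget.health_month),
        "hh_food_month": format_usd(r.household_budget.food_month),
        "hh_other_month": format_usd(r.household_budget.other_month),
    }
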