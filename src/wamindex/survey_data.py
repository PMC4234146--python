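"""Household survey data model and I/O.

One row per surveyed household: a site code, the index child's
height-for-age Z-score (HAZ, computed externally against the WHO 2006
growth reference), maternal education, monthly income in local currency,
binary asset/housing indicators, improved water/sanitation flags and the
deprivation indicators used by the adapted MPI.

HAZ is consumed, never computed, here. Stunting is HAZ strictly below -2.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: WHO biological-plausibility flag for HAZ; records beyond this are
#: treated as data errors rather than real growth deficits.
DEFAULT_HAZ_LIMIT = 6.0

#: Scalar columns every cohort CSV must provide (via the codebook mapping).
REQUIRED_COLUMNS = (
    "household_id",
    "site",
    "haz",
    "child_age_months",
    "child_sex",
    "maternal_education_years",
    "income_local",
    "currency",
    "people_per_room",
    "improved_water",
    "improved_sanitation",
    "any_child_died",
    "electricity",
    "natural_flooring",
    "solid_cooking_fuel",
)


@dataclass
class HouseholdRecord:
    """A single surveyed household and its index child."""

    household_id: str
    site: str
    haz: float | None
    child_age_months: int
    child_sex: int
    maternal_education_years: int
    income_local: float
    currency: str
    assets: dict[str, int | None]
    people_per_room: float
    improved_water: int
    improved_sanitation: int
    any_child_died: int
    electricity: int
    natural_flooring: int
    solid_cooking_fuel: int

    def __post_init__(self) -> None:
        if self.haz is not None and not math.isfinite(self.haz):
            raise ValueError(
                f"household {self.household_id}: haz must be finite or missing"
            )
        if self.income_local < 0:
            raise ValueError(f"household {self.household_id}: negative income")
        if self.people_per_room is not None and self.people_per_room < 0:
            raise ValueError(
                f"household {self.household_id}: negative people_per_room"
            )
        for name, value in self.assets.items():
            if value not in (0, 1, None):
                raise ValueError(
                    f"household {self.household_id}: indicator {name!r} "
                    f"must be 0/1/missing, got {value!r}"
                )


@dataclass
class Cohort:
    """An ordered collection of households sharing one indicator name set."""

    records: list[HouseholdRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.household_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate household_id values: {dupes}")
        names = {frozenset(r.assets) for r in self.records}
        if len(names) > 1:
            raise ValueError("records do not share a common indicator name set")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def indicator_names(self) -> list[str]:
        return sorted(self.records[0].assets) if self.records else []

    @property
    def sites(self) -> list[str]:
        return sorted({r.site for r in self.records})

    def haz_array(self) -> list[float | None]:
        return [r.haz for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {c: getattr(r, c) for c in REQUIRED_COLUMNS}
            for name in self.indicator_names:
                row[f"asset_{name}"] = r.assets[name]
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        # %.17g round-trips float64 exactly, so read(write(c)) == c
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class CurrencyTable:
    """ISO-4217 code -> USD per one unit of local currency, on a stated date."""

    rates: Mapping[str, float]
    as_of: str = ""

    def __post_init__(self) -> None:
        for code, rate in self.rates.items():
            if not rate > 0:
                raise ValueError(f"exchange rate for {code} must be positive")


@dataclass
class ExclusionLog:
    """Counts of records removed by the anthropometric filter."""

    missing_haz: int = 0
    extreme_haz: int = 0
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.missing_haz + self.extreme_haz

    def to_json(self) -> str:
        return json.dumps(
            {
                "missing_haz": self.missing_haz,
                "extreme_haz": self.extreme_haz,
                "total": self.total,
                "excluded_ids": self.excluded_ids,
            },
            sort_keys=True,
        )


def is_stunted(haz: float) -> int:
    """1 iff HAZ lies strictly below -2 (chronic growth deficit).

    A child at exactly -2.00 is *not* stunted: the definition is
    "less than two standard deviations below the median".
    """
    if haz is None or not math.isfinite(haz):
        raise ValueError("haz is missing or non-finite; cannot classify stunting")
    return int(haz < -2.0)


def convert_income_usd(
    income_local: float, currency: str, table: CurrencyTable
) -> float:
    """Convert a local-currency amount to USD with the table's fixed rates."""
    if currency not in table.rates:
        known = ", ".join(sorted(table.rates))
        raise KeyError(f"unknown currency {currency!r}; known codes: {known}")
    return income_local * table.rates[currency]


def filter_anthropometry(
    cohort: Cohort, haz_abs_limit: float = DEFAULT_HAZ_LIMIT
) -> tuple[Cohort, ExclusionLog]:
    """Drop records with missing HAZ, then records with |HAZ| > limit.

    Mirrors the usual cleaning step before growth analyses: missing
    anthropometry cannot be used, and |HAZ| beyond the plausibility limit
    flags measurement or data-entry error. Idempotent.
    """
    if not haz_abs_limit > 0:
        raise ValueError("haz_abs_limit must be positive")
    log = ExclusionLog()
    kept: list[HouseholdRecord] = []
    for r in cohort.records:
        if r.haz is None:
            log.missing_haz += 1
            log.excluded_ids.append(r.household_id)
        elif abs(r.haz) > haz_abs_limit:
            log.extreme_haz += 1
            log.excluded_ids.append(r.household_id)
        else:
            kept.append(r)
    provenance = cohort.provenance
    if log.total:
        provenance = (
            f"{provenance} | filtered |HAZ|<={haz_abs_limit:g}: "
            f"{log.missing_haz} missing, {log.extreme_haz} extreme"
        ).strip(" |")
    return Cohort(records=kept, provenance=provenance), log


def _load_codebook(codebook: str | Path | Mapping) -> dict:
    if isinstance(codebook, Mapping):
        return dict(codebook)
    path = Path(codebook)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _code_indicator(raw, coding: Mapping) -> int | None:
    """Map a raw CSV cell to 0/1/missing via the codebook coding table."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    key = str(raw).strip()
    if key in coding:
        return int(coding[key])
    try:
        value = int(float(key))
    except ValueError:
        return None
    return value if value in (0, 1) else None


def read_cohort(path: str | Path, codebook: str | Path | Mapping) -> Cohort:
    """Read a household CSV using a codebook that maps and codes columns.

    The codebook (YAML/JSON or dict) has:
      ``columns``   — cohort field name -> CSV column name (identity entries
                      may be omitted);
      ``indicators``— list of CSV columns holding binary assets, or a map
                      indicator-name -> CSV column;
      ``coding``    — raw cell value -> 0/1 (e.g. ``{"yes": 1, "no": 0}``),
                      applied to indicator and flag columns;
      ``currency_table`` — optional {code: USD rate} with ``as_of`` date.

    Unparseable indicator cells become missing with a logged warning;
    a missing required column or duplicate household_id is a hard error.
    """
    book = _load_codebook(codebook)
    colmap: dict[str, str] = dict(book.get("columns", {}))
    coding: Mapping = book.get("coding", {"0": 0, "1": 1})
    df = pd.read_csv(
        path,
        dtype={colmap.get("household_id", "household_id"): str},
        float_precision="round_trip",
    )

    for fieldname in REQUIRED_COLUMNS:
        column = colmap.get(fieldname, fieldname)
        if column not in df.columns:
            raise ValueError(f"required column {fieldname!r} (CSV column "
                             f"{column!r}) not found in {path}")

    indicators = book.get("indicators")
    if indicators is None:
        indicators = {
            c[len("asset_"):]: c for c in df.columns if c.startswith("asset_")
        }
    elif isinstance(indicators, list):
        indicators = {c: c for c in indicators}

    records = []
    for _, row in df.iterrows():
        assets: dict[str, int | None] = {}
        for name, column in indicators.items():
            value = _code_indicator(row[column], coding)
            if value is None and not (
                isinstance(row[column], float) and math.isnan(row[column])
            ):
                logger.warning(
                    "household %s: unparseable indicator %s=%r recorded as missing",
                    row[colmap.get("household_id", "household_id")], name,
                    row[column],
                )
            assets[name] = value

        def get(fieldname, cast=None):
            raw = row[colmap.get(fieldname, fieldname)]
            if isinstance(raw, float) and math.isnan(raw):
                return None
            return cast(raw) if cast else raw

        records.append(
            HouseholdRecord(
                household_id=str(get("household_id")),
                site=str(get("site")),
                haz=get("haz", float),
                child_age_months=get("child_age_months", int),
                child_sex=get("child_sex", int),
                maternal_education_years=get("maternal_education_years", int),
                income_local=get("income_local", float),
                currency=str(get("currency")),
                assets=assets,
                people_per_room=get("people_per_room", float),
                improved_water=get("improved_water", int),
                improved_sanitation=get("improved_sanitation", int),
                any_child_died=get("any_child_died", int),
                electricity=get("electricity", int),
                natural_flooring=get("natural_flooring", int),
                solid_cooking_fuel=get("solid_cooking_fuel", int),
            )
        )
    return Cohort(records=records, provenance=f"read from {path}")


def currency_table_from_codebook(codebook: str | Path | Mapping) -> CurrencyTable:
    book = _load_codebook(codebook)
    entry = book.get("currency_table", {})
    rates = entry.get("rates", entry if "as_of" not in entry else {})
    return CurrencyTable(rates=dict(rates), as_of=str(entry.get("as_of", "")))
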