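"""The four comparator wealth measures and the composite WAMI index.

WAMI = (Water/sanitation + Assets + Maternal education + Income) / 32:
four components each scored 0-8 points —

* water/sanitation: 4 points per improved facility (WHO definitions);
* assets: count of the eight priority assets selected by the forest;
* maternal education: completed years (0-16) divided by 2;
* income: monthly household income in USD scored 1-8 by fixed octile
  cutoffs (26 / 47 / 72 / 106 / 135 / 200 / 293 USD).

The comparators are maternal education alone (years), the tetrachoric-PCA
score, an adapted household-level MPI (education, child-death and
living-standard deprivations equally weighted, reported as wealth =
1 - deprivation so all measures point the same way), and the unweighted
priority-asset count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest_selection import asset_score
from .survey_data import Cohort, HouseholdRecord

#: Fixed octile upper bounds in USD for income scores 1..7 (8 is open-ended).
DEFAULT_OCTILE_BOUNDS = (26.0, 47.0, 72.0, 106.0, 135.0, 200.0, 293.0)

EDUCATION_CAP_YEARS = 16
WAMI_TOTAL_POINTS = 32


@dataclass(frozen=True)
class IncomeOctileCutoffs:
    """Strictly increasing USD upper bounds for income scores 1..8."""

    bounds: tuple[float, ...] = DEFAULT_OCTILE_BOUNDS

    def __post_init__(self) -> None:
        if len(self.bounds) != 7:
            raise ValueError("need exactly 7 upper bounds (8th bin is open)")
        if any(b >= a for a, b in zip(self.bounds[1:], self.bounds[:-1])):
            raise ValueError("octile bounds must be strictly increasing")

    @classmethod
    def from_sample(cls, incomes_usd) -> "IncomeOctileCutoffs":
        """Empirical octile bounds (12.5%..87.5% quantiles), rounded to
        2 decimals — for cohorts whose income distribution differs from
        the fixed defaults."""
        incomes = np.asarray(incomes_usd, dtype=float)
        qs = np.quantile(incomes, np.arange(1, 8) / 8.0)
        bounds = tuple(np.round(qs, 2))
        if len(set(bounds)) != 7:
            raise ValueError("sample too concentrated for distinct octiles")
        return cls(bounds=bounds)


@dataclass(frozen=True)
class MpiCutoffs:
    """Deprivation codings for the adapted household-level MPI."""

    education_deprivation_years: int = 5  # deprived if completed years < 5
    asset_list: tuple[str, ...] = (
        "radio", "tv", "mobile_phone", "fridge", "computer",
        "sewing_machine", "iron",
    )
    asset_count_threshold: int = 1  # deprived if owns <= 1 of the 7

    def __post_init__(self) -> None:
        if len(self.asset_list) != 7:
            raise ValueError("MPI asset list must have exactly 7 entries")


@dataclass
class WamiComponents:
    """Point breakdown of one household's WAMI score."""

    water_san_score: int
    asset_score: int
    education_score: float
    income_score: int
    total: float = field(init=False)
    wami: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (self.water_san_score + self.asset_score
                      + self.education_score + self.income_score)
        self.wami = self.total / WAMI_TOTAL_POINTS


@dataclass
class WealthIndex:
    """Per-household scores for one measurement method, plus metadata."""

    method: str
    scores: np.ndarray
    household_ids: list[str]
    metadata: dict = field(default_factory=dict)
    components: list[WamiComponents] | None = None


def education_measure(years: float) -> float:
    """Maternal education comparator: completed years, pass-through."""
    if years < 0:
        raise ValueError("education years cannot be negative")
    return float(years)


def education_score(years: float) -> float:
    """WAMI education component: min(years, 16) / 2, i.e. 0-8 points."""
    if years < 0:
        raise ValueError("education years cannot be negative")
    return min(float(years), float(EDUCATION_CAP_YEARS)) / 2.0


def water_sanitation_score(improved_water: int, improved_sanitation: int) -> int:
    """4 points per improved facility: 0, 4 or 8."""
    if improved_water is None or improved_sanitation is None:
        raise ValueError("improved water/sanitation flags are required")
    return 4 * int(improved_water) + 4 * int(improved_sanitation)


def income_octile_score(
    income_usd: float, cutoffs: IncomeOctileCutoffs = IncomeOctileCutoffs()
) -> int:
    """Score 1..8 from the octile bin of USD income.

    Incomes are rounded to 2 decimals first (the cutoffs form a two-decimal
    lattice: 26.00 scores 1, 26.01 scores 2); bins are upper-inclusive and
    the 8th bin is unbounded.
    """
    if income_usd < 0:
        raise ValueError("income cannot be negative")
    income = round(float(income_usd), 2)
    for score, bound in enumerate(cutoffs.bounds, start=1):
        if income <= bound:
            return score
    return 8


def wami(
    record: HouseholdRecord,
    assets: list[str],
    cutoffs: IncomeOctileCutoffs = IncomeOctileCutoffs(),
    income_usd: float | None = None,
) -> WamiComponents:
    """Composite WAMI score of one household (0..1, attained min 1/32).

    ``income_usd`` may be passed pre-converted; otherwise ``income_local``
    is assumed to already be in USD.
    """
    for name in ("improved_water", "improved_sanitation",
                 "maternal_education_years", "income_local"):
        if getattr(record, name) is None:
            raise ValueError(
                f"household {record.household_id}: missing WAMI component "
                f"input {name!r}"
            )
    income = record.income_local if income_usd is None else income_usd
    return WamiComponents(
        water_san_score=water_sanitation_score(
            record.improved_water, record.improved_sanitation
        ),
        asset_score=asset_score(record, assets),
        education_score=education_score(record.maternal_education_years),
        income_score=income_octile_score(income, cutoffs),
    )


def mpi_wealth(record: HouseholdRecord, cutoffs: MpiCutoffs = MpiCutoffs()) -> float:
    """Adapted MPI reported as wealth in [0, 1].

    Deprivation D averages three equally weighted dimensions: education
    (mother completed fewer than the cutoff years), health (any child in
    the household has died), and living standard (the mean of six
    deprivations: no electricity, unimproved water, unimproved sanitation,
    natural flooring, solid cooking fuel, and ownership of at most
    ``asset_count_threshold`` of the seven listed assets). Returns 1 - D.
    """
    for name in ("maternal_education_years", "any_child_died", "electricity",
                 "improved_water", "improved_sanitation", "natural_flooring",
                 "solid_cooking_fuel"):
        if getattr(record, name) is None:
            raise ValueError(
                f"household {record.household_id}: missing MPI field {name!r}"
            )
    owned = 0
    for name in cutoffs.asset_list:
        value = record.assets.get(name)
        if value is None:
            raise ValueError(
                f"household {record.household_id}: missing MPI asset {name!r}"
            )
        owned += int(value)

    edu_deprived = int(
        record.maternal_education_years < cutoffs.education_deprivation_years
    )
    living = [
        1 - int(record.electricity),
        1 - int(record.improved_water),
        1 - int(record.improved_sanitation),
        int(record.natural_flooring),
        int(record.solid_cooking_fuel),
        int(owned <= cutoffs.asset_count_threshold),
    ]
    deprivation = (edu_deprived + int(record.any_child_died)
                   + sum(living) / 6.0) / 3.0
    return 1.0 - deprivation


METHODS = ("education", "pca", "mpi", "rf_assets", "wami")


def compute_index(
    cohort: Cohort,
    method: str,
    context: dict | None = None,
) -> WealthIndex:
    """Per-household scores for one measurement method.

    ``context`` carries the fitted artifacts a method needs:
    ``pca_index`` (a PcaWealthIndex) for ``pca``; ``selected_assets`` for
    ``rf_assets`` and ``wami``; optional ``octile_cutoffs``, ``mpi_cutoffs``
    and ``income_usd`` (per-household array, else local income is taken as
    USD). Deterministic given the context.
    """
    context = context or {}
    ids = [r.household_id for r in cohort.records]
    income_usd = context.get("income_usd")

    if method == "education":
        scores = np.array([
            education_measure(r.maternal_education_years) for r in cohort
        ])
        return WealthIndex(method, scores, ids)
    if method == "mpi":
        cut = context.get("mpi_cutoffs", MpiCutoffs())
        scores = np.array([mpi_wealth(r, cut) for r in cohort])
        return WealthIndex(method, scores, ids, {"cutoffs": cut})
    if method == "pca":
        pca_index = context.get("pca_index")
        if pca_index is None:
            raise ValueError(
                "method 'pca' requires fitted loadings: run the tetrachoric "
                "PCA first and pass context['pca_index']"
            )
        id_to_score = dict(zip(pca_index.household_ids, pca_index.scores))
        missing = [i for i in ids if i not in id_to_score]
        if missing:
            raise ValueError(f"PCA scores missing for households {missing[:5]}")
        scores = np.array([id_to_score[i] for i in ids])
        return WealthIndex(method, scores, ids,
                           {"loadings": pca_index.loadings,
                            "eigenvalue_share": pca_index.eigenvalue_share})
    if method in ("rf_assets", "wami"):
        assets = context.get("selected_assets")
        if assets is None:
            raise ValueError(
                f"method {method!r} requires a fitted asset set: run the "
                "forest selection first and pass context['selected_assets']"
            )
        if method == "rf_assets":
            scores = np.array([asset_score(r, assets) for r in cohort], float)
            return WealthIndex(method, scores, ids, {"assets": list(assets)})
        cut = context.get("octile_cutoffs", IncomeOctileCutoffs())
        components = [
            wami(r, assets, cut,
                 None if income_usd is None else float(income_usd[i]))
            for i, r in enumerate(cohort)
        ]
        scores = np.array([c.wami for c in components])
        return WealthIndex(method, scores, ids,
                           {"assets": list(assets), "octile_bounds": cut.bounds},
                           components=components)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
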