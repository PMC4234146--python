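"""Indicator screening by prevalence variation and Cronbach's alpha.

Candidate binary wealth indicators are screened in two passes before any
index is built: (1) indicators with too little between-household variation
(fewer than ``min_category_prop`` of households in one category) carry no
information and are dropped; (2) indicators whose removal raises the
scale's internal-consistency reliability (Cronbach's alpha) by more than a
tolerance are dropped iteratively, the classic scale-purification step.
The surviving set feeds both the tetrachoric PCA and the random-forest
selection so that method comparisons start from identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .survey_data import Cohort

DEFAULT_PPR_THRESHOLD = 2.0


@dataclass
class IndicatorMatrix:
    """Households x binary indicators, the substrate for alpha/PCA/forests."""

    values: np.ndarray
    indicator_names: list[str]
    household_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if p != len(self.indicator_names):
            raise ValueError("indicator_names does not match matrix width")
        if n != len(self.household_ids):
            raise ValueError("household_ids does not match matrix height")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("indicator matrix entries must be 0/1")
        self.values = self.values.astype(np.int8)

    @property
    def n_households(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    def prevalence(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.indicator_names.index(name)]

    def subset(self, names: list[str]) -> "IndicatorMatrix":
        idx = [self.indicator_names.index(n) for n in names]
        return IndicatorMatrix(self.values[:, idx], list(names),
                               list(self.household_ids))


@dataclass
class ReliabilityReport:
    """Outcome of the screening pass."""

    alpha_overall: float
    alpha_if_deleted: dict[str, float]
    prevalence: dict[str, float]
    kept: list[str]
    dropped: dict[str, str] = field(default_factory=dict)  # name -> reason

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha_overall": self.alpha_overall,
                "alpha_if_deleted": self.alpha_if_deleted,
                "prevalence": self.prevalence,
                "kept": self.kept,
                "dropped": self.dropped,
            },
            sort_keys=True,
        )


def dichotomize_people_per_room(value: float, threshold: float = DEFAULT_PPR_THRESHOLD) -> int:
    """Code household crowding as an asset-like indicator.

    1 means fewer than ``threshold`` people per room (less crowded, the
    wealthier category), so all indicators point the same way: 1 = better off.
    """
    if value < 0:
        raise ValueError("people_per_room cannot be negative")
    return int(value < threshold)


def build_indicator_matrix(
    cohort: Cohort,
    include_crowding: bool = True,
    ppr_threshold: float = DEFAULT_PPR_THRESHOLD,
) -> IndicatorMatrix:
    """Assemble the binary indicator matrix from a cohort.

    Households with a missing value in any candidate indicator are excluded
    (and would be logged upstream); crowding enters as the dichotomized
    people-per-room indicator.
    """
    names = cohort.indicator_names
    rows, ids = [], []
    for r in cohort.records:
        values = [r.assets[n] for n in names]
        crowd = (
            [dichotomize_people_per_room(r.people_per_room, ppr_threshold)]
            if include_crowding
            else []
        )
        if any(v is None for v in values) or (include_crowding and r.people_per_room is None):
            continue
        rows.append(values + crowd)
        ids.append(r.household_id)
    all_names = list(names) + (["people_per_room"] if include_crowding else [])
    return IndicatorMatrix(np.array(rows, dtype=np.int8), all_names, ids)


def cronbach_alpha(matrix: IndicatorMatrix | np.ndarray) -> float:
    """Cronbach's coefficient alpha of a households x items matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(row sums)),
    with sample (n-1) variances. Equals 1 exactly for duplicated items,
    0 in expectation for independent items.
    """
    values = matrix.values if isinstance(matrix, IndicatorMatrix) else np.asarray(matrix)
    n, k = values.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 indicators")
    if n < 2:
        raise ValueError("alpha needs at least 2 households")
    item_var = values.var(axis=0, ddof=1)
    if np.any(item_var == 0):
        names = (
            matrix.indicator_names
            if isinstance(matrix, IndicatorMatrix)
            else [str(i) for i in range(k)]
        )
        constant = [names[i] for i in np.flatnonzero(item_var == 0)]
        raise ValueError(f"constant indicator column(s): {constant}")
    total_var = values.sum(axis=1).var(ddof=1)
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def alpha_if_deleted(matrix: IndicatorMatrix) -> dict[str, float]:
    """Alpha of each (k-1)-item subscale obtained by deleting one item."""
    out = {}
    for j, name in enumerate(matrix.indicator_names):
        sub = np.delete(matrix.values, j, axis=1)
        out[name] = cronbach_alpha(sub)
    return out


def screen_indicators(
    matrix: IndicatorMatrix,
    min_category_prop: float = 0.10,
    alpha_drop_delta: float = 0.01,
) -> ReliabilityReport:
    """Two-pass indicator screen: prevalence variation, then alpha purification.

    Pass 1 drops indicators with min(prevalence, 1-prevalence) below
    ``min_category_prop``. Pass 2 iteratively drops the indicator whose
    deletion raises alpha the most, while that raise exceeds
    ``alpha_drop_delta``; ties break on indicator name order. Deterministic.
    """
    if not 0 < min_category_prop < 0.5:
        raise ValueError("min_category_prop must lie in (0, 0.5)")

    prevalence = dict(zip(matrix.indicator_names, matrix.prevalence().tolist()))
    dropped: dict[str, str] = {}
    kept = []
    for name in matrix.indicator_names:
        p = prevalence[name]
        if min(p, 1 - p) < min_category_prop:
            dropped[name] = "low_variation"
        else:
            kept.append(name)
    if len(kept) < 2:
        raise ValueError("fewer than 2 indicators survive the variation screen")

    current = matrix.subset(kept)
    alpha = cronbach_alpha(current)
    while current.n_indicators > 2:
        deleted = alpha_if_deleted(current)
        # best candidate: largest raise, name order breaking ties
        best = max(sorted(deleted), key=lambda n: deleted[n])
        if deleted[best] - alpha <= alpha_drop_delta:
            break
        dropped[best] = "alpha_drop"
        kept = [n for n in current.indicator_names if n != best]
        current = current.subset(kept)
        alpha = deleted[best]

    return ReliabilityReport(
        alpha_overall=alpha,
        # item-deleted alpha is undefined once only 2 items remain
        alpha_if_deleted=(alpha_if_deleted(current)
                          if current.n_indicators > 2 else {}),
        prevalence=prevalence,
        kept=list(current.indicator_names),
        dropped=dropped,
    )
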