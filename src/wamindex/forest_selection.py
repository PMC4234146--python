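"""Random-forest asset selection via conditional permutation importance.

A regression forest is grown with child HAZ as the outcome and the
screened binary indicators as predictors. Variable importance is the mean
out-of-bag (OOB) increase in squared error when an indicator is permuted —
but permuted *within strata of correlated indicators* (conditional
permutation importance). Unconditional permutation inflates the apparent
importance of indicators that merely correlate with truly predictive ones;
permuting within strata preserves the indicator's relationship to its
correlates and isolates its own contribution. The top-ranked assets
(fixed k, or a scree-style largest-gap cut) are summed, unweighted, into
the household asset score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .survey_data import HouseholdRecord


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters for the regression forest.

    ``features_per_split=None`` uses the regression default ceil(p/3).
    ``conditional_threshold`` is the |phi| association above which another
    indicator joins the conditioning grid for permutation.
    """

    n_trees: int = 500
    features_per_split: int | None = None
    min_node_size: int = 5
    bootstrap: bool = True
    seed: int = 0
    conditional_threshold: float = 0.2
    max_conditioning_vars: int = 5  # grid capped at 2^5 cells

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")


@dataclass
class Forest:
    """Fitted ensemble with per-tree out-of-bag record tracking."""

    trees: list[DecisionTreeRegressor]
    oob_indices: list[np.ndarray]
    X: np.ndarray  # float32 copy used at fit time
    y: np.ndarray
    indicator_names: list[str]
    config: ForestConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float32)
        return np.mean([t.predict(X, check_input=False) for t in self.trees], axis=0)


@dataclass
class ImportanceRanking:
    """Conditional permutation importances, descending."""

    importances: dict[str, float]  # HAZ-units^2, mean OOB loss increase
    ranking: list[str] = field(init=False)
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # descending importance, name order breaking ties
        self.ranking = sorted(
            sorted(self.importances), key=lambda n: -self.importances[n]
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "indicator": self.ranking,
                "importance": [self.importances[n] for n in self.ranking],
                "rank": range(1, len(self.ranking) + 1),
                "selected": [n in self.selected for n in self.ranking],
            }
        )


def fit_forest(matrix, haz: np.ndarray, config: ForestConfig) -> Forest:
    """Grow a regression forest of HAZ on the binary indicators.

    Trees use variance-reduction splits; each is grown on a bootstrap
    resample (when ``config.bootstrap``) with the held-out records tracked
    as its OOB set. Fully deterministic given ``config.seed``.
    """
    X = np.ascontiguousarray(matrix.values, dtype=np.float32)
    y = np.asarray(haz, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("haz length does not match indicator matrix")
    if np.any(~np.isfinite(y)):
        raise ValueError("haz contains missing/non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("haz is constant: no variance to explain")

    max_features = config.features_per_split or max(1, math.ceil(p / 3))
    rng = np.random.default_rng(config.seed)
    trees, oob_indices = [], []
    for _ in range(config.n_trees):
        tree_seed = int(rng.integers(0, 2**31 - 1))
        if config.bootstrap:
            sample = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), sample)
        else:
            sample = np.arange(n)
            oob = np.array([], dtype=int)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            min_samples_leaf=config.min_node_size,
            random_state=tree_seed,
        )
        tree.fit(X[sample], y[sample])
        trees.append(tree)
        oob_indices.append(oob)
    return Forest(trees=trees, oob_indices=oob_indices, X=X, y=y,
                  indicator_names=list(matrix.indicator_names), config=config)


def _phi_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise phi (Pearson) coefficients between binary columns."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    return np.nan_to_num(corr, nan=0.0)


def _conditioning_strata(
    X: np.ndarray, target: int, threshold: float, max_vars: int
) -> np.ndarray:
    """Stratum label per record for conditional permutation of ``target``.

    Conditioning set = indicators with |phi| association to the target above
    ``threshold``; capped at the ``max_vars`` most associated so the
    cross-classification grid (2^max_vars cells) stays populated. Records in
    the same stratum share the full conditioning pattern.
    """
    phi = _phi_matrix(X)[target]
    phi[target] = 0.0
    candidates = np.flatnonzero(np.abs(phi) > threshold)
    if candidates.size == 0:
        return np.zeros(X.shape[0], dtype=np.int64)
    if candidates.size > max_vars:
        candidates = candidates[np.argsort(-np.abs(phi[candidates]))[:max_vars]]
    weights = 2 ** np.arange(candidates.size)
    return (X[:, candidates].astype(np.int64) @ weights)


def _permute_within_strata(
    values: np.ndarray, strata: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute ``values`` independently within each stratum (vectorized)."""
    n = len(values)
    order_a = np.lexsort((rng.random(n), strata))
    order_b = np.lexsort((rng.random(n), strata))
    out = values.copy()
    out[order_a] = values[order_b]
    return out


def conditional_importance(forest: Forest, conditional: bool = True) -> ImportanceRanking:
    """Conditional permutation importance of every indicator.

    For each tree and indicator: permute the indicator's OOB values within
    the conditioning strata, re-predict, and record the increase in OOB
    squared error over the unpermuted baseline. The importance is the mean
    increase over trees (HAZ-units^2). Requires bootstrap OOB records.
    ``conditional=False`` collapses every stratum grid to a single cell,
    giving plain marginal permutation importance.
    """
    if all(len(o) == 0 for o in forest.oob_indices):
        raise ValueError(
            "no out-of-bag records (bootstrap disabled); conditional "
            "importance requires OOB error"
        )
    X, y = forest.X, forest.y
    n, p = X.shape
    rng = np.random.default_rng(forest.config.seed + 1)

    if conditional:
        strata = [
            _conditioning_strata(
                X, j, forest.config.conditional_threshold,
                forest.config.max_conditioning_vars,
            )
            for j in range(p)
        ]
    else:
        strata = [np.zeros(n, dtype=np.int64)] * p

    deltas = np.zeros(p)
    n_trees_used = 0
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if len(oob) == 0:
            continue
        n_trees_used += 1
        X_oob = np.ascontiguousarray(X[oob])
        y_oob = y[oob]
        base_mse = np.mean((tree.predict(X_oob, check_input=False) - y_oob) ** 2)
        used = set(tree.tree_.feature[tree.tree_.feature >= 0].tolist())
        X_perm = X_oob.copy()
        for j in range(p):
            if j not in used:
                continue  # permuting an unused feature cannot change predictions
            X_perm[:, j] = _permute_within_strata(X_oob[:, j], strata[j][oob], rng)
            pred = tree.predict(X_perm, check_input=False)
            deltas[j] += np.mean((pred - y_oob) ** 2) - base_mse
            X_perm[:, j] = X_oob[:, j]
    importances = dict(zip(forest.indicator_names, (deltas / n_trees_used).tolist()))
    return ImportanceRanking(importances=importances)


def unconditional_importance(forest: Forest) -> ImportanceRanking:
    """Plain (marginal) permutation importance, for contrast with the
    conditional scheme: the indicator is permuted over the whole OOB set."""
    return conditional_importance(forest, conditional=False)


def select_assets(
    ranking: ImportanceRanking, mode: str = "fixed_k", k: int = 8
) -> list[str]:
    """Choose the priority asset set from an importance ranking.

    ``fixed_k`` keeps the top-k indicators (default 8). ``largest_gap``
    applies a scree-style rule: the kept prefix ends just before the largest
    consecutive drop in the ordered importances (earliest gap wins ties).
    """
    if not ranking.ranking:
        raise ValueError("empty importance ranking")
    ordered = ranking.ranking
    if mode == "fixed_k":
        if k <= 0:
            raise ValueError("k must be positive")
        if k > len(ordered):
            raise ValueError(f"k={k} exceeds {len(ordered)} indicators")
        selected = ordered[:k]
    elif mode == "largest_gap":
        values = np.array([ranking.importances[n] for n in ordered])
        gaps = values[:-1] - values[1:]
        cut = int(np.argmax(gaps)) + 1  # earliest maximal gap
        selected = ordered[:cut]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    ranking.selected = list(selected)
    return list(selected)


@dataclass
class AssetScore:
    """Per-household priority-asset counts (0..k) for one asset set."""

    scores: np.ndarray
    household_ids: list[str]
    assets: list[str]

    def __post_init__(self) -> None:
        k = len(self.assets)
        if np.any((self.scores < 0) | (self.scores > k)):
            raise ValueError(f"asset scores must lie in 0..{k}")


def asset_scores(cohort, assets: list[str]) -> AssetScore:
    """Asset score of every household in a cohort."""
    return AssetScore(
        scores=np.array([asset_score(r, assets) for r in cohort]),
        household_ids=[r.household_id for r in cohort],
        assets=list(assets),
    )


def asset_score(record: HouseholdRecord, assets: list[str]) -> int:
    """Unweighted count of owned priority assets (0..k)."""
    total = 0
    for name in assets:
        if name == "people_per_room":
            from .reliability import dichotomize_people_per_room

            value = dichotomize_people_per_room(record.people_per_room)
        else:
            value = record.assets.get(name)
        if value is None:
            raise ValueError(f"household {record.household_id}: indicator "
                             f"{name!r} is missing")
        total += int(value)
    return total
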