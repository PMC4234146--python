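"""Comparison framework for the wealth measures.

Each candidate measure is judged by how well it predicts child HAZ in a
linear model with site indicator variables: (1) mean squared prediction
error from leave-one-out (or k-fold) cross-validation, with the scoring
pipeline optionally refit inside every fold; (2) adjusted R-squared; and
(3) a scaled effect size — the change in HAZ associated with a 25%
increase of the measure across its observed range, so measures on
different scales are comparable. A construct-validity check relates each
measure to log monthly income in USD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .forest_selection import (ForestConfig, conditional_importance,
                               fit_forest, select_assets)
from .indices import (IncomeOctileCutoffs, MpiCutoffs, compute_index)
from .latent_correlation import pca_first_component, tetrachoric_matrix
from .reliability import build_indicator_matrix, screen_indicators
from .survey_data import Cohort, CurrencyTable, convert_income_usd

logger = logging.getLogger(__name__)

RefitFn = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class EffectSize:
    """Change in HAZ per 25% increase of a (min-max scaled) wealth measure."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


@dataclass
class ValidationReport:
    """One measure's row of the comparison table."""

    method: str
    loocv_mse: float
    adjusted_r2: float
    effect_size_25: EffectSize
    n_variables: int
    kfold_mse: float | None = None
    income_assoc: dict | None = None
    extra: dict = field(default_factory=dict)


def _design(score: np.ndarray | None, sites: Sequence[str],
            site_levels: Sequence[str] | None = None,
            include_sites: bool = True) -> np.ndarray:
    """Intercept (+ score) + site dummies (reference = first site level).

    ``score=None`` drops the score term (intercept-only baseline model).
    """
    n = len(sites)
    cols = [np.ones(n)]
    if score is not None:
        cols.append(np.asarray(score, dtype=float))
    if include_sites:
        levels = sorted(set(sites)) if site_levels is None else list(site_levels)
        for level in levels[1:]:
            cols.append(np.array([s == level for s in sites], dtype=float))
    return np.column_stack(cols)


def _ols(y: np.ndarray, X: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    return beta


def loocv_mse(
    haz: np.ndarray,
    score: np.ndarray,
    sites: Sequence[str],
    refit_score: RefitFn | None = None,
    include_site_dummies: bool = True,
) -> float:
    """Leave-one-out cross-validated MSE of the HAZ ~ score (+ site) model.

    Each record in turn is held out; the linear model — and, when
    ``refit_score`` is supplied, the scoring pipeline itself — is refit on
    the remainder and used to predict the held-out HAZ. ``refit_score``
    maps (train_idx, test_idx) to (train_scores, test_scores). A fold whose
    held-out site is absent from training is skipped with a warning and the
    mean is over valid folds.
    """
    y = np.asarray(haz, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 records")
    sites = list(sites)
    errors = []
    for i in range(n):
        train = np.array([j for j in range(n) if j != i])
        if include_site_dummies and sites[i] not in {sites[j] for j in train}:
            warnings.warn(f"fold {i}: site {sites[i]!r} absent from training; "
                          "fold skipped")
            continue
        if refit_score is not None:
            s_train, s_test = refit_score(train, np.array([i]))
        elif score is None:
            s_train = s_test = None
        else:
            s_train, s_test = score[train], np.atleast_1d(score[i])
        levels = sorted({sites[j] for j in train})
        X_train = _design(s_train, [sites[j] for j in train], levels,
                          include_site_dummies)
        X_test = _design(s_test, [sites[i]], levels, include_site_dummies)
        beta = _ols(y[train], X_train)
        errors.append(float((y[i] - (X_test @ beta)[0]) ** 2))
    if not errors:
        raise ValueError("no valid leave-one-out folds")
    return float(np.mean(errors))


def kfold_mse(
    haz: np.ndarray,
    score: np.ndarray,
    sites: Sequence[str],
    k: int = 10,
    seed: int = 0,
    refit_score: RefitFn | None = None,
    include_site_dummies: bool = True,
) -> float:
    """K-fold cross-validated MSE, folds stratified by site.

    Within each site, records are shuffled (from ``seed``) and dealt
    round-robin to folds, so every fold sees every site. ``k = n``
    reduces to leave-one-out.
    """
    y = np.asarray(haz, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    sites = list(sites)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    offset = 0
    for site in sorted(set(sites)):
        idx = np.array([i for i in range(n) if sites[i] == site])
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            fold_of[i] = (offset + pos) % k
        offset += len(idx)

    errors = []
    for fold in range(k):
        test = np.flatnonzero(fold_of == fold)
        train = np.flatnonzero(fold_of != fold)
        if len(test) == 0:
            continue
        train_sites = {sites[j] for j in train}
        valid = np.array([i for i in test if sites[i] in train_sites])
        if len(valid) < len(test):
            warnings.warn(f"fold {fold}: records from unseen sites skipped")
        if len(valid) == 0:
            continue
        if refit_score is not None:
            s_train, s_test = refit_score(train, valid)
        elif score is None:
            s_train = s_test = None
        else:
            s_train, s_test = score[train], score[valid]
        levels = sorted(train_sites)
        X_train = _design(s_train, [sites[j] for j in train], levels,
                          include_site_dummies)
        X_test = _design(s_test, [sites[j] for j in valid], levels,
                         include_site_dummies)
        beta = _ols(y[train], X_train)
        errors.extend(((y[valid] - X_test @ beta) ** 2).tolist())
    return float(np.mean(errors))


def adjusted_r2(haz: np.ndarray, score: np.ndarray, sites: Sequence[str],
                include_site_dummies: bool = True) -> float:
    """Adjusted R-squared of HAZ ~ score + site indicators."""
    y = np.asarray(haz, dtype=float)
    X = _design(score, sites, include_sites=include_site_dummies)
    beta = _ols(y, X)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n, p = X.shape  # p includes the intercept
    r2 = 1.0 - ss_res / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p))


def effect_size_25(
    haz: np.ndarray,
    score: np.ndarray,
    sites: Sequence[str],
    already_unit_scale: bool = False,
    include_site_dummies: bool = True,
) -> EffectSize:
    """HAZ change per 25% increase of the measure's observed range.

    The score is min-max rescaled to [0, 1] over the cohort (measures
    already on a [0, 1] scale, like WAMI, may opt out), HAZ is regressed on
    the scaled score with site indicators, and the effect is 0.25 x slope
    with a 95% CI (t quantile below 100 residual df, 1.96 otherwise).
    The min-max normalization makes the effect invariant to affine
    rescaling of the raw score.
    """
    y = np.asarray(haz, dtype=float)
    s = np.asarray(score, dtype=float)
    if not already_unit_scale:
        span = s.max() - s.min()
        if span == 0:
            raise ValueError("score has zero range; cannot scale")
        s = (s - s.min()) / span
    X = _design(s, sites, include_sites=include_site_dummies)
    beta = _ols(y, X)
    resid = y - X @ beta
    n, p = X.shape
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    slope = float(beta[1])
    if se > 0 and dof > 0:
        t_stat = slope / se
        p_value = float(2 * stats.t.sf(abs(t_stat), dof))
        q = float(stats.t.ppf(0.975, dof)) if dof < 100 else 1.959963984540054
    else:
        p_value = 0.0 if slope != 0 else 1.0
        q = 0.0
    return EffectSize(
        estimate=0.25 * slope,
        ci_low=0.25 * (slope - q * se),
        ci_high=0.25 * (slope + q * se),
        p_value=p_value,
    )


def income_association(
    score: np.ndarray, income_usd: np.ndarray, sites: Sequence[str]
) -> dict:
    """Construct validity: association of a wealth score with log income.

    Household-level Pearson and Spearman correlations of score with
    log(1 + USD income), the OLS slope, and a site-mean table (site as the
    unit of analysis) with the site-level Pearson correlation.
    """
    import pandas as pd

    income = np.asarray(income_usd, dtype=float)
    if np.all(income == 0):
        raise ValueError("all incomes are zero")
    log_income = np.log1p(income)
    s = np.asarray(score, dtype=float)
    pearson = float(stats.pearsonr(s, log_income).statistic)
    spearman = float(stats.spearmanr(s, log_income).statistic)
    slope = float(np.polyfit(log_income, s, 1)[0])

    table = (
        pd.DataFrame({"site": list(sites), "score": s, "log_income": log_income})
        .groupby("site", as_index=False)
        .mean()
        .sort_values("site")
        .reset_index(drop=True)
    )
    site_pearson = (
        float(stats.pearsonr(table["score"], table["log_income"]).statistic)
        if len(table) > 2 else float("nan")
    )
    return {
        "pearson": pearson,
        "spearman": spearman,
        "slope": slope,
        "site_means": table,
        "site_pearson": site_pearson,
    }


@dataclass
class CompareConfig:
    """Configuration of the full comparison pipeline."""

    forest: ForestConfig = field(default_factory=ForestConfig)
    selection_mode: str = "fixed_k"
    n_assets: int = 8
    min_category_prop: float = 0.10
    alpha_drop_delta: float = 0.01
    octile_cutoffs: IncomeOctileCutoffs | None = None  # None = fixed defaults
    empirical_octiles: bool = False
    mpi_cutoffs: MpiCutoffs = field(default_factory=MpiCutoffs)
    currency_table: CurrencyTable | None = None  # None = income already USD
    refit_selection: bool = False
    cv: str = "loocv"  # or "kfold"
    kfold_k: int = 10
    seed: int = 0
    include_site_dummies: bool = True


def fit_context(cohort: Cohort, config: CompareConfig) -> dict:
    """Fit every artifact the measures need on the full cohort.

    Screens indicators, fits the tetrachoric PCA and the forest selection,
    converts incomes to USD and resolves octile cutoffs. Returns the
    context dict consumed by :func:`wamindex.indices.compute_index`,
    with the screening report and importance ranking attached.
    """
    matrix = build_indicator_matrix(cohort)
    if matrix.n_households != len(cohort):
        raise ValueError("records with missing indicators present; filter first")
    report = screen_indicators(matrix, config.min_category_prop,
                               config.alpha_drop_delta)
    kept = matrix.subset(report.kept)
    haz = np.array([r.haz for r in cohort], dtype=float)
    if np.any(~np.isfinite(haz)):
        raise ValueError("cohort contains missing HAZ; filter first")

    tetra = tetrachoric_matrix(kept)
    pca_index = pca_first_component(tetra, kept)

    forest = fit_forest(kept, haz, config.forest)
    ranking = conditional_importance(forest)
    selected = select_assets(ranking, config.selection_mode, config.n_assets)

    if config.currency_table is not None:
        income_usd = np.array([
            convert_income_usd(r.income_local, r.currency, config.currency_table)
            for r in cohort
        ])
    else:
        income_usd = np.array([r.income_local for r in cohort], dtype=float)

    if config.octile_cutoffs is not None:
        octiles = config.octile_cutoffs
    elif config.empirical_octiles:
        octiles = IncomeOctileCutoffs.from_sample(income_usd)
    else:
        octiles = IncomeOctileCutoffs()

    return {
        "reliability_report": report,
        "indicator_matrix": kept,
        "tetrachoric": tetra,
        "pca_index": pca_index,
        "forest": forest,
        "importance_ranking": ranking,
        "selected_assets": selected,
        "octile_cutoffs": octiles,
        "mpi_cutoffs": config.mpi_cutoffs,
        "income_usd": income_usd,
        "haz": haz,
    }


def _refit_fn(cohort: Cohort, method: str, config: CompareConfig,
              context: dict) -> RefitFn | None:
    """Per-fold refit of the scoring pipeline, for refit_selection mode.

    Education and MPI scores are record-local, so no refit is needed. For
    PCA the loadings (and standardization constants) are re-estimated on
    the training fold; for the RF measures the forest and asset selection
    are refit; empirical octile cutoffs are recomputed from training
    incomes.
    """
    if method in ("education", "mpi"):
        return None
    matrix = context["indicator_matrix"]
    haz = context["haz"]
    income_usd = context["income_usd"]
    records = cohort.records

    def refit(train: np.ndarray, test: np.ndarray):
        sub = type(matrix)(matrix.values[train], matrix.indicator_names,
                           [matrix.household_ids[i] for i in train])
        if method == "pca":
            tetra = tetrachoric_matrix(sub)
            idx = pca_first_component(tetra, sub)
            loadings = np.array([idx.loadings[n] for n in sub.indicator_names])
            values = matrix.values.astype(float)
            prevalence = values[train].mean(axis=0)
            sd = values[train].std(axis=0, ddof=1)
            raw = ((values - prevalence) / sd) @ loadings
            mu, sigma = raw[train].mean(), raw[train].std(ddof=1)
            z = (raw - mu) / sigma
            return z[train], z[test]
        forest = fit_forest(sub, haz[train], config.forest)
        ranking = conditional_importance(forest)
        assets = select_assets(ranking, config.selection_mode, config.n_assets)
        cols = [matrix.indicator_names.index(a) for a in assets]
        counts = matrix.values[:, cols].sum(axis=1).astype(float)
        if method == "rf_assets":
            return counts[train], counts[test]
        # wami: recompute octiles from the training incomes if empirical
        octiles = (IncomeOctileCutoffs.from_sample(income_usd[train])
                   if config.empirical_octiles else context["octile_cutoffs"])
        from .indices import wami as wami_fn

        def score_one(i):
            return wami_fn(records[i], assets, octiles,
                           float(income_usd[i])).wami

        return (np.array([score_one(i) for i in train]),
                np.array([score_one(i) for i in test]))

    return refit


def compare_methods(
    cohort: Cohort,
    methods: Sequence[str] = ("education", "pca", "mpi", "rf_assets", "wami"),
    config: CompareConfig | None = None,
    context: dict | None = None,
) -> dict[str, ValidationReport]:
    """Full comparison of wealth measures on one cohort.

    Fits the shared pipeline once, then per method computes cross-validated
    MSE (LOOCV or site-stratified k-fold per ``config.cv``), adjusted R²,
    the 25%-increase effect size, and the income association. Deterministic
    given ``config.seed``.
    """
    config = config or CompareConfig()
    if context is None:
        context = fit_context(cohort, config)
    haz = context["haz"]
    sites = [r.site for r in cohort]
    income_usd = context["income_usd"]

    n_vars = {
        "education": 1,
        "pca": len(context["reliability_report"].kept),
        "mpi": 14,
        "rf_assets": len(context["selected_assets"]),
        "wami": len(context["selected_assets"]) + 4,
    }

    reports: dict[str, ValidationReport] = {}
    for method in methods:
        index = compute_index(cohort, method, context)
        scores = index.scores
        refit = (_refit_fn(cohort, method, config, context)
                 if config.refit_selection else None)
        if config.cv == "kfold":
            mse = kfold_mse(haz, scores, sites, config.kfold_k, config.seed,
                            refit, config.include_site_dummies)
            loo = None
        else:
            mse = loocv_mse(haz, scores, sites, refit,
                            config.include_site_dummies)
            loo = mse
        reports[method] = ValidationReport(
            method=method,
            loocv_mse=mse if loo is not None else float("nan"),
            kfold_mse=mse if config.cv == "kfold" else None,
            adjusted_r2=adjusted_r2(haz, scores, sites,
                                    config.include_site_dummies),
            effect_size_25=effect_size_25(
                haz, scores, sites,
                already_unit_scale=(method == "wami"),
                include_site_dummies=config.include_site_dummies,
            ),
            n_variables=n_vars.get(method, 1),
            income_assoc=income_association(scores, income_usd, sites),
        )
    return reports


def comparison_table(reports: dict[str, ValidationReport]):
    """Reports as a comparison table (one row per measure)."""
    import pandas as pd

    rows = []
    for method, r in reports.items():
        mse = r.loocv_mse if r.kfold_mse is None else r.kfold_mse
        rows.append({
            "method": method,
            "cv_mse": round(mse, 4),
            "adjusted_r2_pct": round(100 * r.adjusted_r2, 2),
            "effect_size_25": round(r.effect_size_25.estimate, 3),
            "ci_low": round(r.effect_size_25.ci_low, 3),
            "ci_high": round(r.effect_size_25.ci_high, 3),
            "p_value": r.effect_size_25.p_value,
            "n_variables": r.n_variables,
            "income_pearson": round(r.income_assoc["pearson"], 3)
            if r.income_assoc else None,
        })
    return pd.DataFrame(rows)
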