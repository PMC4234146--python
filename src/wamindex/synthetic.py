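"""Synthetic multicountry household cohorts with known ground truth.

The generator emulates the statistical structure the SES analyses assume:
each household has a latent wealth level (site-specific mean and SD, so
sites form low/middle/high groups); binary assets arise by thresholding a
probit factor model on standardized latent wealth — which makes the
tetrachoric correlation of any two assets *exactly* the product of their
loadings, so tetrachoric estimation is a genuine parameter-recovery test.
Maternal education, income (log-normal, in a site-specific local currency),
water/sanitation coverage, crowding and child mortality are all linked to
the same latent wealth. Child HAZ is linear in the standardized count of a
designated subset of "signal" assets (plus an optional independent
water/sanitation effect) with Gaussian noise, and site intercepts are
calibrated so the expected stunting proportion matches a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .survey_data import Cohort, CurrencyTable, HouseholdRecord

#: Overall ownership proportions the probit thresholds are solved for.
DEFAULT_ASSET_PREVALENCE = {
    "iron": 0.55, "mattress": 0.58, "chair": 0.61, "sofa": 0.35,
    "cupboard": 0.45, "table": 0.57, "radio": 0.50, "computer": 0.12,
    "tv": 0.63, "sewing_machine": 0.20, "mobile_phone": 0.70,
    "fridge": 0.31, "bank_account": 0.31, "separate_kitchen": 0.50,
    "electricity": 0.80,
    # a near-universal-absence asset, present so the variation screen
    # has something to drop
    "car": 0.04,
}

DEFAULT_SIGNAL_ASSETS = (
    "mattress", "chair", "table", "tv", "fridge", "mobile_phone",
    "bank_account", "separate_kitchen",
)

DEFAULT_SITES = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8")

#: Latent wealth means per site: a high pair, a middle group, a low group.
DEFAULT_SITE_WEALTH_MEANS = (1.1, 0.5, 0.45, 0.4, -0.3, -0.45, -0.8, -1.4)

DEFAULT_SITE_CURRENCIES = ("BRL", "PEN", "ZAR", "NPR", "BDT", "PKR", "INR", "TZS")

DEFAULT_CURRENCY_RATES = {
    "BRL": 0.57, "PEN": 0.35, "ZAR": 0.135, "NPR": 0.0135,
    "BDT": 0.0145, "PKR": 0.0118, "INR": 0.0215, "TZS": 0.00075,
    "USD": 1.0,
}

#: Improved water / improved sanitation baseline coverage per site: high
#: nearly everywhere, with one low-coverage site and a couple of partial ones.
DEFAULT_WATER_PROBS = (0.99, 0.97, 0.65, 0.98, 0.99, 0.98, 0.97, 0.28)
DEFAULT_SANITATION_PROBS = (0.98, 0.84, 0.84, 0.97, 0.96, 0.74, 0.37, 0.05)

#: HAZ grand intercept frozen from calibrate_stunting(target=0.42) at
#: n=80_000; see docs/methods.md.
DEFAULT_HAZ_INTERCEPT = -1.9551


def default_currency_table() -> CurrencyTable:
    return CurrencyTable(rates=dict(DEFAULT_CURRENCY_RATES), as_of="2010-01-01")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator (seed mandatory)."""

    seed: int = 0
    n_sites: int = 8
    n_per_site: int = 100
    sites: tuple[str, ...] = DEFAULT_SITES
    site_wealth_means: tuple[float, ...] = DEFAULT_SITE_WEALTH_MEANS
    site_wealth_sd: float = 0.6
    asset_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASSET_PREVALENCE))
    asset_loading: float = 0.7
    signal_assets: tuple[str, ...] = DEFAULT_SIGNAL_ASSETS
    true_effect: float = 0.4       # HAZ SD per SD of the signal-asset count
    #: if set, overrides true_effect with a per-asset HAZ coefficient:
    #: HAZ gains this much per owned signal asset (Z-score = SD units)
    signal_asset_effect: float | None = None
    wash_effect: float = 0.15      # HAZ per improved facility, beyond wealth
    haz_noise_sd: float = 1.15
    haz_intercept: float = DEFAULT_HAZ_INTERCEPT
    haz_site_slope: float = 0.3    # extra site-level HAZ per latent-mean unit
    education_base: float = 6.5
    education_site_slope: float = 1.8
    education_wealth_slope: float = 2.0
    education_noise_sd: float = 2.2
    income_log_base: float = math.log(90.0)   # median ~90 USD/month
    income_site_slope: float = 0.35
    income_wealth_slope: float = 0.55
    income_log_sd: float = 0.6
    water_probs: tuple[float, ...] = DEFAULT_WATER_PROBS
    sanitation_probs: tuple[float, ...] = DEFAULT_SANITATION_PROBS
    wash_wealth_slope: float = 0.25
    site_currencies: tuple[str, ...] = DEFAULT_SITE_CURRENCIES
    target_stunting: float = 0.42

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for probs in (self.water_probs, self.sanitation_probs):
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError("probabilities must lie in [0, 1]")
        for p in self.asset_prevalence.values():
            if not 0 < p < 1:
                raise ValueError("asset prevalences must lie in (0, 1)")
        if not self.site_wealth_sd > 0 or not self.haz_noise_sd > 0:
            raise ValueError("SDs must be positive")
        if not set(self.signal_assets) <= set(self.asset_prevalence):
            raise ValueError("signal_assets must be a subset of the assets")

    @property
    def n_signal_assets(self) -> int:
        return len(self.signal_assets)


@dataclass
class SyntheticTruth:
    """Generator ground truth aligned with the emitted cohort."""

    latent_wealth: np.ndarray
    standardized_wealth: np.ndarray
    ses_driver: np.ndarray  # standardized signal-asset count used in the HAZ model
    true_effect: float
    signal_assets: tuple[str, ...]
    asset_thresholds: dict[str, float]
    haz_site_intercepts: dict[str, float]


def _population_moments(config: GeneratorConfig) -> tuple[float, float]:
    """Analytic mean/SD of latent wealth over the equal-size site mixture."""
    means = np.asarray(config.site_wealth_means[: config.n_sites])
    mu = float(means.mean())
    var = float(config.site_wealth_sd**2 + (means**2).mean() - mu**2)
    return mu, math.sqrt(var)


def implied_asset_prevalence(config: GeneratorConfig, threshold: float) -> float:
    """P(asset owned) under the probit factor model for a given threshold.

    The asset's latent index is ``loading * z + sqrt(1-loading^2) * eps``
    with z the standardized latent wealth (site mixture of normals), so the
    implied prevalence is the mixture average of normal tail probabilities.
    """
    lam = config.asset_loading
    mu, sd = _population_moments(config)
    means = np.asarray(config.site_wealth_means[: config.n_sites])
    z_mu = (means - mu) / sd
    z_sd = config.site_wealth_sd / sd
    index_sd = math.sqrt(lam**2 * z_sd**2 + (1 - lam**2))
    return float(np.mean(stats.norm.sf(threshold, loc=lam * z_mu, scale=index_sd)))


def asset_thresholds(config: GeneratorConfig) -> dict[str, float]:
    """Probit thresholds solved so implied prevalences hit the targets."""
    out = {}
    for name, target in config.asset_prevalence.items():
        out[name] = float(optimize.brentq(
            lambda t: implied_asset_prevalence(config, t) - target, -8.0, 8.0
        ))
    return out


def generate(config: GeneratorConfig) -> tuple[Cohort, SyntheticTruth]:
    """Generate one cohort plus its ground truth. Deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    sites = list(config.sites[: config.n_sites])
    means = config.site_wealth_means[: config.n_sites]
    n = config.n_sites * config.n_per_site
    mu_pop, sd_pop = _population_moments(config)
    thresholds = asset_thresholds(config)
    asset_names = sorted(config.asset_prevalence)
    lam = config.asset_loading
    resid = math.sqrt(1 - lam**2)

    site_of = np.repeat(np.arange(config.n_sites), config.n_per_site)
    w = np.concatenate([
        m + config.site_wealth_sd * rng.standard_normal(config.n_per_site)
        for m in means
    ])
    z = (w - mu_pop) / sd_pop

    assets = {}
    for name in asset_names:
        index = lam * z + resid * rng.standard_normal(n)
        assets[name] = (index > thresholds[name]).astype(int)

    education = np.clip(np.round(
        config.education_base
        + config.education_site_slope * np.asarray(means)[site_of]
        + config.education_wealth_slope * z
        + config.education_noise_sd * rng.standard_normal(n)
    ), 0, 16).astype(int)

    income_usd = np.exp(
        config.income_log_base
        + config.income_site_slope * np.asarray(means)[site_of]
        + config.income_wealth_slope * z
        + config.income_log_sd * rng.standard_normal(n)
    )
    rates = default_currency_table()
    currencies = [config.site_currencies[s] for s in site_of]
    income_local = np.array([
        usd / rates.rates[c] for usd, c in zip(income_usd, currencies)
    ])

    def probit_flag(base_probs, slope):
        base = stats.norm.ppf(np.asarray(base_probs)[site_of])
        return (rng.random(n) < stats.norm.cdf(base + slope * z)).astype(int)

    water = probit_flag(config.water_probs, config.wash_wealth_slope)
    sanitation = probit_flag(config.sanitation_probs, config.wash_wealth_slope)
    child_died = (rng.random(n) < stats.norm.cdf(-1.2 - 0.3 * z)).astype(int)
    flooring = (rng.random(n) < stats.norm.cdf(
        stats.norm.ppf(0.45) - 0.8 * z)).astype(int)
    fuel = (rng.random(n) < stats.norm.cdf(
        stats.norm.ppf(0.55) - 0.8 * z)).astype(int)
    ppr = np.exp(0.55 - 0.35 * z + 0.45 * rng.standard_normal(n))
    age = rng.integers(24, 61, size=n)
    sex = (rng.random(n) < 0.52).astype(int)

    if config.n_signal_assets > 0:
        signal_count = np.sum(
            [assets[a] for a in config.signal_assets], axis=0
        ).astype(float)
        ses = (signal_count - signal_count.mean()) / signal_count.std(ddof=1)
        if config.signal_asset_effect is not None:
            # per-asset coefficient mode: effect per SD implied by the count SD
            effect_per_sd = (config.signal_asset_effect
                             * signal_count.std(ddof=1))
        else:
            effect_per_sd = config.true_effect
    else:
        ses = np.zeros(n)
        effect_per_sd = 0.0

    intercepts = {
        site: config.haz_intercept + config.haz_site_slope * m
        for site, m in zip(sites, means)
    }
    haz = (
        np.array([intercepts[sites[s]] for s in site_of])
        + effect_per_sd * ses
        + config.wash_effect * (water + sanitation)
        + config.haz_noise_sd * rng.standard_normal(n)
    )

    records = []
    for i in range(n):
        site = sites[site_of[i]]
        records.append(HouseholdRecord(
            household_id=f"{site}-{i % config.n_per_site + 1:03d}",
            site=site,
            haz=float(haz[i]),
            child_age_months=int(age[i]),
            child_sex=int(sex[i]),
            maternal_education_years=int(education[i]),
            income_local=float(income_local[i]),
            currency=currencies[i],
            assets={name: int(assets[name][i]) for name in asset_names},
            people_per_room=float(ppr[i]),
            improved_water=int(water[i]),
            improved_sanitation=int(sanitation[i]),
            any_child_died=int(child_died[i]),
            electricity=int(assets["electricity"][i]),
            natural_flooring=int(flooring[i]),
            solid_cooking_fuel=int(fuel[i]),
        ))
    cohort = Cohort(records=records,
                    provenance=f"synthetic cohort, seed={config.seed}")
    truth = SyntheticTruth(
        latent_wealth=w,
        standardized_wealth=z,
        ses_driver=ses,
        true_effect=float(effect_per_sd),
        signal_assets=tuple(config.signal_assets),
        asset_thresholds=thresholds,
        haz_site_intercepts=intercepts,
    )
    return cohort, truth


def calibrate_stunting(
    config: GeneratorConfig,
    n_sim: int = 10_000,
    tolerance: float = 0.02,
    seed: int | None = None,
) -> GeneratorConfig:
    """Shift the HAZ grand intercept so expected stunting hits the target.

    Simulates a large cohort (>= ``n_sim`` households, same per-site split)
    and bisects the intercept until the simulated stunting proportion is
    within ``tolerance`` of ``config.target_stunting``. Targets of exactly
    0 or 1 are unattainable under Gaussian noise.
    """
    target = config.target_stunting
    if not 0 < target < 1:
        raise ValueError("target stunting must lie strictly inside (0, 1)")
    per_site = max(config.n_per_site, math.ceil(n_sim / config.n_sites))
    sim_seed = config.seed if seed is None else seed
    base = replace(config, n_per_site=per_site, seed=sim_seed)

    def stunting_at(intercept: float) -> float:
        cohort, _ = generate(replace(base, haz_intercept=intercept))
        haz = np.array([r.haz for r in cohort])
        return float(np.mean(haz < -2.0))

    lo, hi = config.haz_intercept - 6.0, config.haz_intercept + 6.0
    if not (stunting_at(lo) > target > stunting_at(hi)):
        raise ValueError("target stunting unattainable within intercept range")
    for _ in range(60):
        mid = (lo + hi) / 2.0
        rate = stunting_at(mid)
        if abs(rate - target) <= tolerance / 2:
            break
        if rate > target:
            lo = mid
        else:
            hi = mid
    return replace(config, haz_intercept=float(mid))


def fixture_800(seed: int = 0, haz_abs_limit: float = 6.0) -> Cohort:
    """An 800-household cohort with exactly 1 missing-HAZ record and 10
    records beyond the |HAZ| filter limit, for exercising the
    anthropometric filter (retains 789).

    Naturally extreme draws are first pulled back inside the limit so the
    planted exclusions are exactly the intended eleven.
    """
    cohort, _ = generate(GeneratorConfig(seed=seed))
    rng = np.random.default_rng(seed + 1)
    chosen = rng.choice(len(cohort.records), size=11, replace=False)
    records = []
    for i, r in enumerate(cohort.records):
        haz = r.haz
        if abs(haz) > haz_abs_limit:
            haz = math.copysign(haz_abs_limit - 0.01, haz)
        if i == chosen[0]:
            haz = None
        elif i in chosen[1:]:
            sign = 1.0 if (i % 2 == 0) else -1.0
            haz = sign * (haz_abs_limit + 0.5 + (i % 7) / 10.0)
        records.append(replace(r, haz=haz))
    return Cohort(records=records,
                  provenance=f"synthetic filter fixture, seed={seed}")
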