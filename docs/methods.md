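# Methods

This note records the statistical models `wamindex` implements, the
defaults it ships, and the judgement calls made where the methodology is
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and filtering

A cohort is one row per household: site code, the index child's HAZ
(computed externally against the WHO 2006 growth reference — this package
never derives Z-scores from raw anthropometry), maternal education years,
monthly income in local currency with an ISO-4217 code, binary
asset/housing indicators, improved water/sanitation flags (WHO
definitions), and the MPI deprivation fields (any child died, electricity,
natural flooring, solid cooking fuel).

Filtering removes records with missing HAZ, then records with |HAZ| above
a configurable plausibility limit. The limit defaults to 6, the
conventional WHO flagging bound for height-for-age; studies citing a
different extreme-value rule can pass their own. Stunting is strict:
HAZ < −2 exactly at the boundary is *not* stunted, following the "less
than two standard deviations" definition. Income conversion uses a fixed
exchange-rate table with a stated as-of date; no inflation adjustment.

Missing-data policy: a household missing any input of a requested index is
ineligible for that index and surfaces as an error naming the field, not a
silent drop. Real multicountry surveys are rarely complete; imputation is
deliberately out of scope.

## Indicator screening

Two passes, in this order:

1. **Variation**: drop indicators with min(p, 1−p) < 0.10 — an asset
   nearly everyone or no one owns cannot separate households.
2. **Internal consistency**: Cronbach's α with sample variances; while
   deleting some item would raise α by more than δ (default 0.01), delete
   the item with the largest raise, ties broken by name order. The
   iterative form was chosen over a single pass because a one-shot rule
   can strand items that only become deleterious after another item
   leaves; with δ = 0.01 the two coincide on well-behaved scales.

Both thresholds are arguments, not constants. The screen is fully
deterministic.

## Tetrachoric PCA

Pearson correlations of 0/1 indicators (phi coefficients) are attenuated
by the margins and can produce spurious "difficulty factors" in PCA. The
package therefore estimates, for each indicator pair, the correlation of a
latent standard bivariate normal dichotomized at the margins — the
tetrachoric correlation — by two-step maximum likelihood: thresholds fixed
at Φ⁻¹ of the margins, ρ maximized over the multinomial likelihood of the
2×2 table (bounded scalar optimization, |ρ| ≤ 0.999). Tables with an empty
cell have no finite MLE; they receive a 0.5 continuity correction on all
cells and a boundary flag. Pairwise estimates need not form a PSD matrix;
if the smallest eigenvalue is below −1e−8 the matrix is repaired by
eigenvalue clipping with the diagonal renormalized to 1, and flagged.

Scoring follows the asset-index convention: the first eigenvector
(unit norm) weights indicators standardized by sample prevalence and SD,
and the resulting score is standardized to mean 0, SD 1 over the cohort.
The eigenvector's sign is fixed so the anchor indicator — by default the
one most correlated with total asset ownership — loads positively, making
"more assets → higher score" the invariant orientation. A numerically
multiple leading eigenvalue raises an error asking for an explicit anchor
rather than returning an arbitrary component.

## Forest-based asset selection

A regression forest of HAZ on the screened indicators: variance-reduction
trees grown on bootstrap resamples with out-of-bag (OOB) tracking.
Defaults are the conventional regression-forest choices — 500 trees,
⌈p/3⌉ candidate features per split, minimum node size 5 — since the
method's origin specifies none; all are in `ForestConfig` and the seed is
mandatory.

Importance is **conditional permutation importance**: for each tree, an
indicator's OOB values are permuted *within strata* defined by the
cross-classification of covariates whose |phi| association with it exceeds
0.2 (capped at the 5 most associated, so the grid has at most 32 cells and
strata stay populated), and the importance is the mean OOB squared-error
increase. Permuting within strata preserves the indicator's relationship
to its correlates, so an asset that merely shadows a predictive one gains
little — the defining contrast with marginal permutation importance, which
the package also exposes for comparison. Two notes on fidelity:

* The selection is supervised — HAZ is the forest outcome. A
  proximity-based unsupervised variant is intentionally not implemented.
* Permutations are vectorized (two stratified lexsorts), keeping the
  16-indicator × 500-tree computation around a second at n = 800.

Selection is top-k (default k = 8) or a scree-style largest-gap rule: keep
the prefix ending just before the largest consecutive drop in ordered
importances, earliest gap on ties. The household wealth score is the
*unweighted count* of selected assets owned — simplicity is the point of
the forest arm.

## The comparator indices and WAMI

* **Education**: mother's completed years, used raw.
* **MPI (adapted, household level)**: deprivation is the equal-weight mean
  of education (< 5 completed years; the cutoff follows the UNDP
  years-of-schooling convention and is configurable), health (any child
  died), and living standard (mean of six items: no electricity,
  unimproved water, unimproved sanitation, natural flooring, solid cooking
  fuel, owning ≤ 1 of a configured 7-asset list). Reported as wealth
  1 − D so all five measures point the same way.
* **WAMI**: water/sanitation (4 points per improved facility) + asset
  count (0–8) + education years/2 (capped at 16 years, so data beyond the
  stated 0–16 range cannot break the component bound) + income octile
  score, all divided by 32. The income octiles are the fixed USD cutoffs
  26/47/72/106/135/200/293 with upper-inclusive bounds on a two-decimal
  lattice (26.00 → 1, 26.01 → 2; incomes are rounded to 2 decimals first).
  Because the income component scores 1–8 rather than 0–8, WAMI's
  attainable range is [1/32, 1]; the package implements the published
  cutoff table literally instead of silently rescaling. For cohorts whose
  income distribution differs from the original study's,
  `IncomeOctileCutoffs.from_sample` recomputes empirical octiles.

## Comparison framework

All evaluation regressions are OLS of HAZ on the (scaled) score plus site
indicator variables with the first site as reference. Site dummies are
included everywhere — including cross-validation — for a single consistent
evaluation model; `include_site_dummies=False` ablates them.

* **LOOCV MSE**: explicit fold loop; with `refit_selection` the scoring
  pipeline itself (PCA loadings and standardization, forest fit and asset
  selection, empirical octiles) is re-estimated inside every fold. Without
  refitting, the loop provably equals the closed-form PRESS/hat-matrix
  statistic, which the tests assert to 1e−10 relative error. A fold whose
  held-out site is absent from training is skipped with a warning.
* **k-fold MSE**: site-stratified round-robin assignment from the seed;
  k = n reduces to LOOCV.
* **Adjusted R²**: 1 − (1−R²)(n−1)/(n−p−1).
* **Effect of a 25% increase**: scores are min–max scaled to [0, 1] over
  the cohort (WAMI, already a 0–1 share, is used as-is), and the effect is
  0.25 × the OLS slope, with a 95% CI using the t quantile below 100
  residual df and 1.96 otherwise. Min–max scaling makes the effect
  invariant to affine transformations of the raw score; "25% of the
  observed range" is the operationalization chosen since measures live on
  unrelated scales.
* **Income association**: Pearson and Spearman correlation of score with
  log(1+USD income) at household level, plus a site-mean table with the
  site-level correlation (site as the unit of analysis).

`compare_methods` defaults to `refit_selection=False` for every method:
at n ≈ 800 the screened set, loadings and selected assets are stable, and
per-fold forest refits would multiply the cost by the sample size for no
change in ranking. The refit path is implemented, tested at small n, and a
flag away.

## Synthetic cohort generator

The generator is the package's test bed, built so each analysis stage is a
parameter-recovery exercise:

* **Latent wealth** w ~ Normal(mₛ, 0.6) with site means
  (1.1, 0.5, 0.45, 0.4, −0.3, −0.45, −0.8, −1.4) — a high pair, a middle
  group, and a low tail, the typical multicountry pattern.
* **Assets** arise by thresholding λ·z + √(1−λ²)·ε (z standardized wealth,
  λ = 0.7), so any two assets' population tetrachoric correlation is
  exactly λ² — tetrachoric estimation recovers a known parameter, not a
  convenience. Thresholds are solved numerically against the site-mixture
  distribution so overall prevalences hit stated targets (16 realistic
  indicators, 4%–80%); a 4%-prevalence "car" exists so the variation
  screen has real work.
* **HAZ** = site intercept + β·(standardized count of 8 signal assets) +
  0.15·(improved water + improved sanitation) + Normal(0, 1.15), with
  β = 0.4 by default, matching the effect magnitudes such studies report.
  `signal_asset_effect` switches to a per-asset coefficient
  parameterization (used by the recovery tests at 0.5 SD per asset). The
  grand intercept −1.9551 was frozen from `calibrate_stunting`
  (bisection on an 80 000-household simulation) so expected stunting is
  42%; site intercepts tilt 0.3 per latent-mean unit so site stunting
  spans roughly 10–60%.
* **Education, income, water/sanitation, crowding, child mortality** are
  all probit- or log-linearly linked to the same latent wealth, with
  site-specific currencies converted through a fixed rate table.

What the generator does **not** emulate: item-level missingness, survey
nonresponse, within-site clustering beyond the site mean, measurement
error in income reporting, and site-specific asset meanings. Passing tests
therefore demonstrate statistical correctness of the machinery under the
assumed latent-factor world, not field validity of any particular index on
real survey data.

## Problem sizes and numerics

Tests and the acceptance script run cohorts of 800 households (8 × 100),
forests of 300–500 trees, and 20-replicate blocks for stochastic claims —
sizes at which each full pipeline fit takes a few seconds and the
complete suite a few minutes, while keeping recovery probabilities high
enough that 18-of-20 criteria are meaningful. Tetrachoric optimization
uses bounded Brent with 1e−6 tolerance; all simulation draws flow from a
single `numpy` Generator per operation, seeded explicitly, so every
artifact is bit-reproducible from (inputs, config, seed).

## Known limitations

* Tetrachoric estimation assumes latent bivariate normality; gross
  violations (e.g. true mixture ownership processes) bias ρ̂.
* Conditional importance conditions on a thresholded, capped covariate set,
  not the full conditional distribution; with > 5 strong correlates some
  shared signal leaks back in.
* The fixed income octiles encode one study population's distribution;
  using them unchanged on richer or poorer cohorts compresses the income
  component (use empirical octiles instead).
* Effect sizes are associations from observational cross-sections with
  site fixed effects; no causal reading is supported.
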