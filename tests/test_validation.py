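import numpy as np
import pytest
from scipy import stats

from wamindex import (CompareConfig, ForestConfig, GeneratorConfig,
                      adjusted_r2, compare_methods, comparison_table,
                      default_currency_table, effect_size_25, generate,
                      income_association, kfold_mse, loocv_mse)


def press_mse(y, X):
    """Independent closed-form LOOCV oracle via hat-matrix leverages."""
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    resid = y - H @ y
    return float(np.mean((resid / (1 - np.diag(H))) ** 2))


def toy_regression(n=60, seed=0, n_sites=3, slope=0.8, noise=0.5):
    rng = np.random.default_rng(seed)
    sites = [f"S{i % n_sites}" for i in range(n)]
    score = rng.standard_normal(n)
    site_shift = np.array([0.4 * (i % n_sites) for i in range(n)])
    y = -1.0 + slope * score + site_shift + noise * rng.standard_normal(n)
    return y, score, sites


class TestLoocv:
    def test_perfect_linear_single_site_gives_zero(self):
        score = np.arange(10, dtype=float)
        y = -1.5 + 0.3 * score
        assert loocv_mse(y, score, ["S1"] * 10) == pytest.approx(0, abs=1e-18)

    def test_matches_press_hat_matrix_oracle(self):
        y, score, sites = toy_regression(seed=3)
        levels = sorted(set(sites))
        X = np.column_stack(
            [np.ones(len(y)), score]
            + [[s == lv for s in sites] for lv in levels[1:]])
        ours = loocv_mse(y, score, sites)
        assert ours == pytest.approx(press_mse(y, X.astype(float)), rel=1e-10)

    def test_intercept_only_two_points(self):
        # each fold predicts the other observation: error 2 both times
        mse = loocv_mse(np.array([0.0, 2.0]), None, ["S1", "S1"])
        assert mse == pytest.approx(4.0)

    def test_refit_hook_receives_fold_indices(self):
        y, score, sites = toy_regression(n=20, seed=4)
        seen = []

        def refit(train, test):
            seen.append((len(train), len(test)))
            return score[train], score[test]

        loocv_mse(y, score, sites, refit_score=refit)
        assert seen == [(19, 1)] * 20

    def test_singleton_site_fold_skipped_with_warning(self):
        y, score, _ = toy_regression(n=10, seed=5)
        sites = ["A"] * 9 + ["B"]
        with pytest.warns(UserWarning, match="absent"):
            mse = loocv_mse(y, score, sites)
        assert np.isfinite(mse)


class TestKfold:
    def test_k_equals_n_is_loocv(self):
        y, score, sites = toy_regression(n=30, seed=6)
        assert kfold_mse(y, score, sites, k=30, seed=0) == pytest.approx(
            loocv_mse(y, score, sites))

    def test_perfect_linear_gives_zero(self):
        score = np.arange(20, dtype=float)
        y = 2 * score
        assert kfold_mse(y, score, ["S1"] * 20, k=5, seed=1) == pytest.approx(
            0, abs=1e-18)

    def test_seeds_agree_within_sampling_noise(self):
        y, score, sites = toy_regression(n=400, seed=7)
        m1 = kfold_mse(y, score, sites, k=10, seed=1)
        m2 = kfold_mse(y, score, sites, k=10, seed=2)
        assert m1 != m2
        assert abs(m1 - m2) < 0.1 * m1

    def test_k_exceeding_n_rejected(self):
        y, score, sites = toy_regression(n=10)
        with pytest.raises(ValueError):
            kfold_mse(y, score, sites, k=11, seed=0)


class TestAdjustedR2:
    def test_exact_fit_single_site(self):
        score = np.arange(10, dtype=float)
        assert adjusted_r2(2 * score, score, ["S1"] * 10) == pytest.approx(1.0)

    def test_independent_score_near_zero(self):
        rng = np.random.default_rng(8)
        n = 800
        y = rng.standard_normal(n)
        score = rng.standard_normal(n)
        sites = [f"S{i % 8}" for i in range(n)]
        assert adjusted_r2(y, score, sites) == pytest.approx(0, abs=0.02)

    def test_six_point_dataset_matches_hand_formula(self):
        y = np.array([1.0, 2.0, 2.5, 3.5, 4.0, 6.0])
        score = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        sites = ["A", "A", "A", "B", "B", "B"]
        # closed form on the explicit design matrix
        X = np.column_stack([np.ones(6), score, [0, 0, 0, 1, 1, 1]]).astype(float)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r2 = 1 - np.sum((y - X @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
        expected = 1 - (1 - r2) * 5 / (6 - 3)
        assert adjusted_r2(y, score, sites) == pytest.approx(expected, rel=1e-12)


class TestEffectSize25:
    def test_exact_linear_closed_form(self):
        score = np.linspace(3, 11, 40)  # range 8, min-max absorbs it
        scaled = (score - 3) / 8
        y = -1 + 2.0 * scaled
        effect = effect_size_25(y, score, ["S1"] * 40)
        assert effect.estimate == pytest.approx(0.5)
        assert effect.ci_low == pytest.approx(0.5)
        assert effect.p_value < 1e-10

    def test_invariant_to_affine_rescaling(self):
        y, score, sites = toy_regression(seed=9)
        a = effect_size_25(y, score, sites)
        b = effect_size_25(y, 7.3 * score - 11.0, sites)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-10)
        assert a.ci_low == pytest.approx(b.ci_low, rel=1e-9)

    def test_uncorrelated_score_ci_covers_zero(self):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(300)
        score = rng.standard_normal(300)
        effect = effect_size_25(y, score, ["S1"] * 300)
        assert effect.covers(0.0)
        assert abs(effect.estimate) < 0.2

    def test_recovers_generating_slope(self):
        cohort, truth = generate(GeneratorConfig(seed=21, wash_effect=0.0))
        haz = np.array([r.haz for r in cohort])
        sites = [r.site for r in cohort]
        effect = effect_size_25(haz, truth.ses_driver, sites)
        target = 0.25 * truth.true_effect * np.ptp(truth.ses_driver)
        assert effect.covers(target)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            effect_size_25(np.arange(5.0), np.ones(5), ["S1"] * 5)


class TestIncomeAssociation:
    def test_exact_log_relation_gives_unit_correlation(self):
        income = np.exp(np.linspace(2, 7, 50)) - 1
        score = np.log1p(income)
        out = income_association(score, income, ["S1"] * 50)
        assert out["pearson"] == pytest.approx(1.0)
        assert out["spearman"] == pytest.approx(1.0)

    def test_permuted_incomes_kill_association(self):
        rng = np.random.default_rng(12)
        income = np.exp(rng.normal(4, 1, size=500))
        score = np.log1p(income)
        shuffled = rng.permutation(income)
        out = income_association(score, shuffled, ["S1"] * 500)
        assert abs(out["pearson"]) < 0.1

    def test_site_mean_table_one_row_per_site(self):
        out = income_association(np.arange(6.0), np.arange(1.0, 7.0),
                                 ["A", "A", "A", "B", "B", "B"])
        assert list(out["site_means"]["site"]) == ["A", "B"]

    def test_all_zero_incomes_rejected(self):
        with pytest.raises(ValueError):
            income_association(np.arange(4.0), np.zeros(4), ["S1"] * 4)


@pytest.fixture(scope="module")
def reports():
    cohort, _ = generate(GeneratorConfig(seed=2))
    config = CompareConfig(forest=ForestConfig(n_trees=200, seed=2),
                           seed=2, currency_table=default_currency_table())
    return compare_methods(cohort, config=config)


class TestCompareMethods:
    def test_one_report_per_method(self, reports):
        assert set(reports) == {"education", "pca", "mpi", "rf_assets", "wami"}
        table = comparison_table(reports)
        assert len(table) == 5

    def test_single_method_single_row(self):
        cohort, _ = generate(GeneratorConfig(seed=2, n_per_site=30))
        config = CompareConfig(forest=ForestConfig(n_trees=50, seed=2), seed=2)
        reports = compare_methods(cohort, methods=["education"], config=config)
        assert len(comparison_table(reports)) == 1

    def test_asset_methods_beat_education_on_mse(self, reports):
        assert reports["pca"].loocv_mse <= reports["education"].loocv_mse
        assert reports["rf_assets"].loocv_mse <= reports["education"].loocv_mse

    def test_wami_effect_exceeds_assets_alone(self, reports):
        # water/sanitation carries independent HAZ signal in the generator
        assert (reports["wami"].effect_size_25.estimate
                > reports["rf_assets"].effect_size_25.estimate)

    def test_ci_contains_point_estimate(self, reports):
        for r in reports.values():
            assert r.effect_size_25.ci_low <= r.effect_size_25.estimate
            assert r.effect_size_25.estimate <= r.effect_size_25.ci_high
            assert r.loocv_mse >= 0
            assert r.adjusted_r2 <= 1

    def test_refit_selection_inside_folds(self):
        """Selection-inside-the-fold LOOCV runs and stays close to the
        fixed-selection result on a small cohort."""
        cohort, _ = generate(GeneratorConfig(seed=4, n_per_site=12))
        config = CompareConfig(forest=ForestConfig(n_trees=30, seed=4),
                               seed=4, refit_selection=True)
        fixed = CompareConfig(forest=ForestConfig(n_trees=30, seed=4), seed=4)
        a = compare_methods(cohort, methods=["rf_assets"], config=config)
        b = compare_methods(cohort, methods=["rf_assets"], config=fixed)
        assert np.isfinite(a["rf_assets"].loocv_mse)
        assert a["rf_assets"].loocv_mse == pytest.approx(
            b["rf_assets"].loocv_mse, rel=0.5)
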