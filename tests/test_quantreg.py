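"""Quantile-regression solver: oracles, recovery, and distributional structure."""

from itertools import combinations

import numpy as np
import pytest

import esbalance as eb
from esbalance.quantreg import bootstrap_se, check_loss, significance_stars, with_bootstrap_se


def brute_force_quantile_loss(y, X, theta):
    """Minimal check loss over all basic solutions (exact fits through p
    points), the classic LAD/quantile vertex property; valid for small n, p."""
    n, p = X.shape
    best = np.inf
    for idx in combinations(range(n), p):
        A = X[list(idx)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        beta = np.linalg.solve(A, y[list(idx)])
        best = min(best, check_loss(theta, y - X @ beta))
    return best


def _intercept_design(y):
    y = np.asarray(y, dtype=float)
    return eb.RegressionDesign(y, np.ones((len(y), 1)), ("intercept",))


class TestFitQuantile:
    def test_median_of_outlier_sample(self):
        design = _intercept_design([1, 2, 3, 4, 100])
        fit = eb.fit_quantile(design, 0.5)
        assert fit.beta[0] == pytest.approx(3.0)

    @pytest.mark.parametrize("theta", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_intercept_only_attains_empirical_quantile_loss(self, theta, rng):
        y = rng.normal(size=41)
        design = _intercept_design(y)
        fit = eb.fit_quantile(design, theta)
        loss_at_quantile = check_loss(theta, y - np.quantile(y, theta))
        assert fit.objective <= loss_at_quantile + 1e-8

    def test_one_covariate_matches_point_pair_search(self):
        y = np.array([1.0, 2.1, 2.9, 4.2, 5.1, 5.9, 7.2, 30.0])
        x = np.arange(1.0, 9.0)
        X = np.column_stack([np.ones(8), x])
        design = eb.RegressionDesign(y, X, ("intercept", "x"))
        fit = eb.fit_quantile(design, 0.5)
        assert fit.objective <= brute_force_quantile_loss(y, X, 0.5) + 1e-8

    @pytest.mark.parametrize("theta", [0.25, 0.5, 0.8])
    def test_random_small_problems_reach_vertex_minimum(self, theta, rng):
        for _ in range(10):
            n = int(rng.integers(5, 11))
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.normal(size=n)
            design = eb.RegressionDesign(y, X, ("intercept", "x"))
            fit = eb.fit_quantile(design, theta)
            assert fit.objective <= brute_force_quantile_loss(y, X, theta) + 1e-8

    def test_invalid_theta(self):
        design = _intercept_design([1.0, 2.0, 3.0])
        for theta in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError, match="theta"):
                eb.fit_quantile(design, theta)

    def test_scale_equivariance_in_y(self, rng):
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
        y = rng.normal(size=60)
        d1 = eb.RegressionDesign(y, X, ("intercept", "a", "b"))
        d2 = eb.RegressionDesign(3.5 * y, X, ("intercept", "a", "b"))
        b1 = eb.fit_quantile(d1, 0.3).beta
        b2 = eb.fit_quantile(d2, 0.3).beta
        assert np.allclose(b2, 3.5 * b1, atol=1e-7)

    def test_median_close_to_ols_under_symmetric_noise(self):
        df = eb.generate_regression_dataset(800, np.zeros(11), noise_sd=0.5, seed=9)
        design = eb.RegressionDesign.from_frame(df)
        ols = eb.fit_ols(design)
        med = eb.fit_quantile(design, 0.5)
        assert np.all(np.abs(med.beta - ols.beta) <= 2 * ols.se)

    def test_agrees_with_statsmodels_quantreg(self, rng):
        """Independent cross-check: the LP optimum is at least as good as
        statsmodels' IRLS solution and the coefficients agree."""
        import statsmodels.api as sm

        X = np.column_stack([np.ones(120), rng.normal(size=(120, 2))])
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.standard_t(df=3, size=120)
        design = eb.RegressionDesign(y, X, ("intercept", "a", "b"))
        ours = eb.fit_quantile(design, 0.5)
        ref = sm.QuantReg(y, X).fit(q=0.5)
        assert ours.objective <= check_loss(0.5, y - X @ ref.params) + 1e-8
        assert np.allclose(ours.beta, ref.params, atol=1e-3)


class TestFitOls:
    def test_noiseless_exact_recovery(self):
        beta = np.array([1.0, -8.0, -4.0, -12.0, -2.0, -1.5, 6.0, 1.0, -0.5, 0.5, -0.3])
        df = eb.generate_regression_dataset(60, beta, noise_sd=0.0, seed=4)
        fit = eb.fit_ols(eb.RegressionDesign.from_frame(df))
        assert np.allclose(fit.beta, beta, atol=1e-9)

    def test_constant_response(self):
        X = np.column_stack([np.ones(20), np.linspace(0, 1, 20)])
        design = eb.RegressionDesign(np.full(20, 7.0), X, ("intercept", "x"))
        fit = eb.fit_ols(design)
        assert fit.beta[0] == pytest.approx(7.0)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        design = eb.RegressionDesign(y, X, ("intercept", "a", "b", "c"))
        fit = eb.fit_ols(design)
        resid = y - X @ fit.beta
        assert np.allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(eb.RankDeficiencyError, match="x2"):
            eb.RegressionDesign(np.zeros(30), X, ("intercept", "x1", "x2"))


class TestQuantilePath:
    def test_location_shift_slopes_stable_across_theta(self):
        beta = np.array([0.5, -3.0, 2.0, -1.0, 0.8, -0.6, 1.2, -0.4, 0.3, -0.2, 0.1])
        df = eb.generate_regression_dataset(400, beta, noise_sd=0.2, seed=12)
        design = eb.RegressionDesign.from_frame(df)
        path = eb.quantile_path(design, thetas=(0.2, 0.5, 0.8), n_boot=100, seed=0)
        for j in range(1, design.p):  # slopes only; the intercept absorbs the shift
            betas = [path.fits[t].beta[j] for t in (0.2, 0.5, 0.8)]
            ses = [path.fits[t].se[j] for t in (0.2, 0.5, 0.8)]
            for b, s in zip(betas, ses):
                assert abs(b - beta[j]) <= 3 * s

    def test_heteroscedastic_scale_covariate_slope_grows_with_theta(self, rng):
        """Noise sd proportional to a covariate makes that covariate's
        coefficient rise with the quantile level."""
        n = 500
        x = rng.uniform(0.1, 1.0, size=n)
        z = rng.uniform(0, 1, size=n)
        y = 1.0 + 2.0 * x + 0.5 * z + x * rng.normal(0, 2.0, size=n)
        X = np.column_stack([np.ones(n), x, z])
        design = eb.RegressionDesign(y, X, ("intercept", "x", "z"))
        thetas = (0.1, 0.3, 0.5, 0.7, 0.9)
        slopes = [eb.fit_quantile(design, t).beta[1] for t in thetas]
        assert np.all(np.diff(slopes) > 0)

    def test_sign_structure_recovery(self):
        """Negative built-up coefficients and positive ecological ones are
        recovered with >= 95% sign accuracy at n = 500."""
        beta = np.array([1.0, -8.5, -4.7, -12.1, -1.8, -1.7, 6.7, 0.9, -0.7, 0.7, -0.4])
        hits = total = 0
        for seed in range(10):
            df = eb.generate_regression_dataset(500, beta, noise_sd=0.1, seed=seed)
            design = eb.RegressionDesign.from_frame(df)
            med = eb.fit_quantile(design, 0.5)
            hits += int(np.sum(np.sign(med.beta[1:]) == np.sign(beta[1:])))
            total += len(beta) - 1
        assert hits / total >= 0.95

    def test_single_theta_path(self):
        df = eb.generate_regression_dataset(60, np.zeros(11), noise_sd=0.3, seed=2)
        design = eb.RegressionDesign.from_frame(df)
        path = eb.quantile_path(design, thetas=(0.5,), n_boot=50, seed=1)
        assert list(path.fits) == [0.5]
        frame = path.to_frame()
        assert "q0.5" in frame.columns and "OLS" in frame.columns

    def test_bootstrap_se_deterministic(self):
        df = eb.generate_regression_dataset(80, np.zeros(11), noise_sd=0.3, seed=3)
        design = eb.RegressionDesign.from_frame(df)
        a = bootstrap_se(design, 0.5, n_boot=30, seed=7)
        b = bootstrap_se(design, 0.5, n_boot=30, seed=7)
        assert np.array_equal(a, b)

    def test_crossing_diagnostics_counts(self, rng):
        x = rng.uniform(0.1, 1.0, 80)
        y = x + rng.normal(0, 0.1, 80)
        X = np.column_stack([np.ones(80), x])
        design = eb.RegressionDesign(y, X, ("intercept", "x"))
        path = eb.quantile_path(design, thetas=(0.2, 0.5, 0.8), n_boot=10, seed=0)
        assert path.crossing_count(design.X) >= 0


def test_significance_star_thresholds():
    assert significance_stars(0.005) == "***"
    assert significance_stars(0.03) == "**"
    assert significance_stars(0.07) == "*"
    assert significance_stars(0.2) == ""


def test_with_bootstrap_se_attaches_pvalues():
    df = eb.generate_regression_dataset(100, np.zeros(11), noise_sd=0.3, seed=8)
    design = eb.RegressionDesign.from_frame(df)
    fit = with_bootstrap_se(eb.fit_quantile(design, 0.5), design, n_boot=40, seed=2)
    assert fit.se is not None and (fit.se > 0).all()
    assert ((fit.pvalues >= 0) & (fit.pvalues <= 1)).all()
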