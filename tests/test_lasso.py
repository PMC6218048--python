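"""LASSO solver, penalty grid, repeated-holdout CV, reference models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pclasso as p
from pclasso.lasso import select_lambda_min

TOY_X = np.array([[1.0], [-1.0]])
TOY_Y = np.array([1.0, -1.0])


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        X = rng.normal(3.0, 2.0, size=(50, 4))
        Z, rec = p.standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(rec.apply(X), Z, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        with pytest.warns(UserWarning, match="constant"):
            Z, rec = p.standardize(X, names=("a", "b"))
        assert rec.names == ("a",)
        assert Z.shape == (20, 1)

    def test_all_constant_rejected(self):
        with pytest.raises(p.ValidationError):
            p.standardize(np.ones((10, 2)))


class TestLassoSolve:
    def test_closed_form_single_predictor_path(self):
        # (1/2)*2*(1-b)^2 + lam*b  ->  b = 1 - lam/2 on [0, 2]
        for lam in np.linspace(0.0, 2.0, 9):
            m = p.lasso_solve(TOY_X, TOY_Y, lam)
            assert m.betas[0] == pytest.approx(max(1.0 - lam / 2.0, 0.0), abs=1e-10)
        assert p.lasso_solve(TOY_X, TOY_Y, 1.0).betas[0] == pytest.approx(0.5, abs=1e-10)

    def test_lambda_zero_equals_ols(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(size=30)
        m = p.lasso_solve(X, y, 0.0)
        coef = np.linalg.lstsq(np.column_stack([np.ones(30), X]), y, rcond=None)[0]
        np.testing.assert_allclose(m.betas, coef[1:], atol=1e-6)
        assert m.beta0 == pytest.approx(coef[0], abs=1e-6)

    def test_intercept_only_at_lambda_max(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, _ = p.standardize(r.normal(size=(25, 6)))
            y = r.normal(size=25)
            lmax = p.lambda_max(X, y)
            m = p.lasso_solve(X, y, lmax)
            assert m.n_active == 0
            assert m.beta0 == pytest.approx(y.mean(), abs=1e-10)

    def test_kkt_conditions(self, rng):
        for _ in range(10):
            X = rng.normal(size=(20, 5))
            y = rng.normal(size=20)
            lam = rng.uniform(0.5, 5.0)
            m = p.lasso_solve(X, y, lam)
            assert p.kkt_residual(m, X, y) < 1e-6

    def test_sklearn_cross_check(self, rng):
        # independent implementation: sklearn minimizes 1/(2N)*RSS + alpha*L1,
        # so alpha = lambda / N matches this objective
        from sklearn.linear_model import Lasso

        X, _ = p.standardize(rng.normal(size=(40, 5)))
        y = X[:, 0] * 2 - X[:, 2] + rng.normal(size=40)
        for lam in (0.5, 4.0, 15.0):
            ours = p.lasso_solve(X, y, lam)
            sk = Lasso(alpha=lam / 40, tol=1e-12, max_iter=200000).fit(X, y)
            np.testing.assert_allclose(ours.betas, sk.coef_, atol=1e-7)

    def test_negative_lambda_rejected(self):
        with pytest.raises(p.ValidationError):
            p.lasso_solve(TOY_X, TOY_Y, -0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        lam_frac=st.floats(0.0, 1.5, allow_nan=False),
        n=st.integers(6, 30),
        j=st.integers(1, 6),
    )
    def test_kkt_holds_for_random_problems(self, seed, lam_frac, n, j):
        """Subgradient optimality holds at every returned solution."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, j))
        y = rng.normal(size=n) * rng.uniform(0.5, 3.0)
        lam = lam_frac * max(p.lambda_max(X, y), 1e-9)
        model = p.lasso_solve(X, y, lam)
        assert p.kkt_residual(model, X, y) < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 20.0, allow_nan=False))
    def test_active_set_shrinks_with_outcome_invariant_scaling(self, seed, scale):
        """Scaling y by c scales the whole solution path by c: the active set
        at lambda is the active set at c*lambda for outcome c*y."""
        rng = np.random.default_rng(seed)
        X, _ = p.standardize(rng.normal(size=(20, 4)))
        y = X @ rng.normal(size=4) + rng.normal(size=20)
        lam = 0.4 * p.lambda_max(X, y)
        a = p.lasso_solve(X, y, lam)
        b = p.lasso_solve(X, scale * y, scale * lam)
        np.testing.assert_allclose(b.betas, scale * a.betas, atol=1e-6 * scale)


class TestLambdaMaxAndGrid:
    def test_toy_lambda_max(self):
        assert p.lambda_max(TOY_X, TOY_Y) == pytest.approx(2.0, abs=1e-10)

    def test_constant_outcome_gives_zero(self):
        assert p.lambda_max(TOY_X, np.array([3.0, 3.0])) == 0.0

    def test_homogeneous_in_outcome_scale(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        assert p.lambda_max(X, -4.0 * y) == pytest.approx(4.0 * p.lambda_max(X, y))

    def test_grid_shape_and_spacing(self):
        grid = p.lambda_grid(2.0, steps=100)
        assert len(grid) == 101
        assert grid[0] == 0.0 and grid[-1] == 2.0
        np.testing.assert_allclose(np.diff(grid), 0.02, atol=1e-12)
        assert np.all(np.diff(grid) >= 0)

    def test_degenerate_grid_warns(self):
        with pytest.warns(UserWarning, match="all zeros"):
            grid = p.lambda_grid(0.0)
        assert np.all(grid == 0.0)


class TestSplitsAndCV:
    def test_holdout_size_rule(self):
        splits = p.make_splits(40, 25, 0.3, seed=0)
        assert all(len(te) == 12 and len(tr) == 28 for tr, te in splits)
        for tr, te in splits:
            assert len(np.intersect1d(tr, te)) == 0

    def test_cv_deterministic(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        a = p.repeated_holdout_cv(X, y, n_splits=40, seed=3)
        b = p.repeated_holdout_cv(X, y, n_splits=40, seed=3)
        np.testing.assert_array_equal(a.mse_split, b.mse_split)
        assert a.lambda_min == b.lambda_min
        assert a.lambda_min in a.lambda_grid

    def test_lambda_max_matches_constant_reference_per_split(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + rng.normal(size=30)
        splits = p.make_splits(30, 30, 0.3, seed=5)
        cv = p.repeated_holdout_cv(X, y, splits=splits)
        const, _ = p.fit_reference_models(X[:, 0], y, splits)
        np.testing.assert_allclose(cv.mse_split[:, -1], const.mse_split, atol=1e-10)

    def test_small_training_split_rejected(self, rng):
        X = rng.normal(size=(10, 7))
        y = rng.normal(size=10)
        with pytest.raises(p.ValidationError, match="too small"):
            p.repeated_holdout_cv(X, y, n_splits=5, holdout_fraction=0.3)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(p.ValidationError):
            p.repeated_holdout_cv(rng.normal(size=(8, 2)), rng.normal(size=8))


class TestSelectLambdaMin:
    def test_unique_interior_minimum(self):
        grid = np.linspace(0, 2, 5)
        mse = np.array([3.0, 1.0, 0.5, 1.2, 4.0])
        assert select_lambda_min(mse, grid) == 2

    def test_flat_curve_prefers_largest(self):
        grid = np.linspace(0, 2, 5)
        assert select_lambda_min(np.ones(5), grid) == 4

    def test_tie_prefers_larger_lambda(self):
        grid = np.linspace(0, 2, 5)
        mse = np.array([2.0, 1.0, 3.0, 1.0, 2.0])
        assert select_lambda_min(mse, grid) == 3


class TestReferenceModels:
    def test_constant_model_arithmetic(self):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        y = np.array([0.0, 2.0, 0.0, 2.0])
        splits = p.make_splits(4, 10, 0.5, seed=0)
        const, br = p.fit_reference_models(x, y, splits)
        assert const.full_coef[0] == pytest.approx(1.0)
        assert const.mse_all == pytest.approx(1.0)  # biased variance of [0,2,0,2]
        # outcome exactly linear in the predictor: exact fit
        assert br.mse_all == pytest.approx(0.0, abs=1e-10)

    def test_constant_mse_all_is_biased_variance(self, rng):
        y = rng.normal(2.0, 3.0, size=24)
        x = rng.normal(size=24)
        splits = p.make_splits(24, 5, 0.3, seed=1)
        const, _ = p.fit_reference_models(x, y, splits)
        assert const.mse_all == pytest.approx(float(np.var(y)), abs=1e-12)


class TestCoefficientSignificance:
    def test_inactive_inputs_have_no_pvalue(self, rng):
        X = rng.normal(size=(40, 3))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.1, size=40)
        cv = p.repeated_holdout_cv(X, y, names=("a", "b", "c"), n_splits=40, seed=2)
        frame = p.coefficient_significance(cv, X, y)
        assert frame.attrs["pvalue_method"] == "ols_refit_active_set"
        inactive = [n for n in ("a", "b", "c") if n not in cv.retained_terms]
        for n in inactive:
            assert np.isnan(frame.loc[n, "pvalue"])
        assert frame.loc["a", "pvalue"] < 1e-6

    def test_noiseless_single_input_pvalue_bounded(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = 2.0 * X[:, 0] + 1.0
        cv = p.repeated_holdout_cv(X, y, names=("a",), n_splits=20, seed=0)
        frame = p.coefficient_significance(cv, X, y)
        pv = frame.loc["a", "pvalue"]
        assert np.isfinite(pv) and 0.0 < pv < 1e-10

    def test_planted_signals_significant(self, basis4):
        # outcome generated from patterns 1 and 3: both flagged at 0.05
        hits = 0
        for seed in range(10):
            spec = p.default_cohort_spec(4, seed=seed)
            _, truth = p.sample_cohort(spec, basis4)
            cv = p.repeated_holdout_cv(
                truth.better, truth.lms_better,
                names=("PC1", "PC2", "PC3", "PC4"), n_splits=50, seed=seed,
            )
            frame = p.coefficient_significance(cv, truth.better, truth.lms_better)
            ok = frame.loc["PC1", "pvalue"] < 0.05 and frame.loc["PC3", "pvalue"] < 0.05
            hits += bool(ok)
        assert hits >= 9
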