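"""L1-penalized least squares (LASSO) with repeated-holdout cross-validation.

The fitted models predict a clinical metric y from principal-component scores
(and optional covariates).  The objective, with an unpenalized intercept, is

    (1/2) * sum_n (y_n - b0 - sum_j x_nj b_j)^2  +  lambda * sum_j |b_j|

solved by cyclic coordinate descent with soft thresholding.  The penalty is
scale-sensitive, so predictors are z-scored before fitting; in cross-validation
the standardization is recomputed on each training split.

Model selection follows a repeated random holdout protocol: the penalty grid
runs linearly from 0 to lambda_max (the smallest penalty with an empty active
set, ``max_j |sum_n x_nj (y_n - ybar)|``); for each grid value the data are
split many times into 70% training / 30% test sets; lambda_min is the grid
value minimizing the mean test MSE (ties broken toward the larger, sparser
penalty), and MSE_all is the full-data error of the full-data fit at
lambda_min.  At lambda -> 0 the solution coincides with ordinary least
squares; at lambda >= lambda_max it is intercept-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FitError, ValidationError

DEFAULT_N_SPLITS = 500
DEFAULT_HOLDOUT = 0.3
DEFAULT_GRID_STEPS = 100


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizationRecord:
    """Per-column mean/SD used to z-score a design matrix; reapplies to new data."""

    means: np.ndarray
    sds: np.ndarray
    names: tuple[str, ...]

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.names):
            raise ValidationError(
                f"expected {len(self.names)} columns, got {X.shape[1]}"
            )
        return (X - self.means) / self.sds


def _default_names(j: int) -> tuple[str, ...]:
    return tuple(f"x{i + 1}" for i in range(j))


def standardize(
    design_matrix: np.ndarray, names: Sequence[str] | None = None
) -> tuple[np.ndarray, StandardizationRecord]:
    """Z-score columns; constant columns are dropped with a warning."""
    X = np.asarray(design_matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("design matrix must be 2-D")
    names = tuple(names) if names is not None else _default_names(X.shape[1])
    if len(names) != X.shape[1]:
        raise ValidationError("one name per design column required")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    keep = sds > 1e-12
    if not keep.any():
        raise ValidationError("all design columns are constant")
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
    record = StandardizationRecord(
        means=means[keep], sds=sds[keep], names=tuple(n for n, k in zip(names, keep) if k)
    )
    return (X[:, keep] - record.means) / record.sds, record


def _standardize_safe(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale without dropping: a zero-variance column gets unit scale
    (it becomes identically zero, so its coefficient is necessarily zero)."""
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 1e-12, sds, 1.0)
    return (X - means) / sds, means, sds


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


@dataclass
class LassoModel:
    """A fitted L1-penalized linear model (intercept unpenalized)."""

    beta0: float
    betas: np.ndarray
    lambda_: float
    names: tuple[str, ...]
    record: StandardizationRecord | None = None

    @property
    def active_set(self) -> tuple[str, ...]:
        return tuple(n for n, b in zip(self.names, self.betas) if b != 0.0)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.betas))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict from data on the same scale the model was fitted on."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.beta0 + X @ self.betas


def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def _cd_solve(
    gram: np.ndarray,
    corr: np.ndarray,
    lam: float,
    beta: np.ndarray,
    tol: float = 1e-8,
    max_sweeps: int = 10000,
) -> np.ndarray:
    """Cyclic coordinate descent on (1/2) b'Gb - c'b + lam*|b|_1 (centered form)."""
    j = len(corr)
    diag = np.diag(gram)
    for sweep in range(max_sweeps):
        delta = 0.0
        for k in range(j):
            if diag[k] <= 0.0:
                continue
            rho = corr[k] - gram[k] @ beta + diag[k] * beta[k]
            new = _soft(rho, lam) / diag[k]
            d = abs(new - beta[k])
            if d > delta:
                delta = d
            beta[k] = new
        if delta < tol:
            if lam > 0:
                # a predictor exactly at the subgradient boundary can keep a
                # floating-point-epsilon coefficient; snap it to zero
                beta[np.abs(beta) * np.maximum(diag, 1.0) <= 1e-10 * lam] = 0.0
            return beta
    raise FitError(
        f"coordinate descent did not converge in {max_sweeps} sweeps "
        f"(lambda={lam}, last max coefficient change {delta:.3e})"
    )


def lasso_solve(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_sweeps: int = 10000,
    beta_init: np.ndarray | None = None,
    record: StandardizationRecord | None = None,
) -> LassoModel:
    """Minimize (1/2)*RSS + lambda*L1 by cyclic coordinate descent.

    ``X`` is used as given (standardize beforehand; the penalty is
    scale-sensitive).  The intercept is unpenalized and recovered from the
    column means.  Converged when the largest coefficient change in a sweep
    falls below ``tol``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y must have the same number of rows")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValidationError("non-finite values in X or y")
    if lambda_ < 0:
        raise ValidationError("lambda must be nonnegative")
    names = tuple(names) if names is not None else _default_names(X.shape[1])

    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    xc = X - x_means
    yc = y - y_mean
    gram = xc.T @ xc
    corr = xc.T @ yc
    beta = (
        np.zeros(X.shape[1])
        if beta_init is None
        else np.asarray(beta_init, dtype=float).copy()
    )
    beta = _cd_solve(gram, corr, float(lambda_), beta, tol=tol, max_sweeps=max_sweeps)
    beta0 = y_mean - float(x_means @ beta)
    return LassoModel(
        beta0=beta0, betas=beta, lambda_=float(lambda_), names=names, record=record
    )


def kkt_residual(model: LassoModel, X: np.ndarray, y: np.ndarray) -> float:
    """Largest violation of the subgradient optimality conditions.

    For active j, ``sum_n x_nj r_n = lambda * sign(b_j)``; for inactive j,
    ``|sum_n x_nj r_n| <= lambda``; returns the max absolute violation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = np.asarray(y, dtype=float).ravel() - model.predict(X)
    grad = X.T @ r
    worst = 0.0
    for j, b in enumerate(model.betas):
        if b != 0.0:
            worst = max(worst, abs(grad[j] - model.lambda_ * np.sign(b)))
        else:
            worst = max(worst, max(0.0, abs(grad[j]) - model.lambda_))
    return float(worst)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an empty active set: ``max_j |x_j . (y - ybar)|``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    yc = np.asarray(y, dtype=float).ravel()
    yc = yc - yc.mean()
    if X.shape[1] == 0:
        return 0.0
    return float(np.max(np.abs(X.T @ yc)))


def lambda_grid(lambda_max_value: float, steps: int = DEFAULT_GRID_STEPS) -> np.ndarray:
    """Linear grid of ``steps + 1`` penalties from 0 to lambda_max inclusive."""
    if lambda_max_value < 0:
        raise ValidationError("lambda_max must be nonnegative")
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    if lambda_max_value == 0:
        warnings.warn("lambda_max is 0; the penalty grid is all zeros", stacklevel=2)
    return np.linspace(0.0, lambda_max_value, steps + 1)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    tol: float = 1e-8,
    max_sweeps: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve along a penalty grid with warm starts (largest penalty first).

    Returns ``(betas, intercepts)`` with ``betas[g]`` the coefficients at
    ``grid[g]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    xc = X - x_means
    yc = y - y_mean
    gram = xc.T @ xc
    corr = xc.T @ yc

    order = np.argsort(grid)[::-1]
    betas = np.zeros((len(grid), X.shape[1]))
    beta = np.zeros(X.shape[1])
    for g in order:
        beta = _cd_solve(gram, corr, float(grid[g]), beta, tol=tol, max_sweeps=max_sweeps)
        betas[g] = beta
    intercepts = y_mean - betas @ x_means
    return betas, intercepts


# ---------------------------------------------------------------------------
# repeated-holdout cross-validation
# ---------------------------------------------------------------------------


def make_splits(
    n: int, n_splits: int, holdout_fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent random train/test splits; a single master seed spawns
    one child seed per split.  Test size is ``round(holdout_fraction * n)``."""
    if not 0 < holdout_fraction < 1:
        raise ValidationError("holdout_fraction must be in (0, 1)")
    n_test = int(round(holdout_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValidationError(f"holdout of {n_test} from {n} samples is unusable")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_splits)
    splits = []
    for s in child_seeds:
        rng = np.random.default_rng(int(s))
        test = rng.choice(n, size=n_test, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        splits.append((np.nonzero(mask)[0], np.sort(test)))
    return splits


@dataclass
class CVResult:
    """Repeated-holdout cross-validation result for one model family."""

    names: tuple[str, ...]
    lambda_grid: np.ndarray
    mse_split: np.ndarray  # (n_splits, n_grid) test MSE per split per penalty
    mse_test_mean: np.ndarray  # (n_grid,)
    mse_test_se: np.ndarray  # (n_grid,)
    lambda_min: float
    lambda_min_index: int
    mse_all: float
    coef_split: np.ndarray  # (n_splits, J) standardized coefficients at lambda_min
    coef_mean: np.ndarray  # (J,)
    coef_sd: np.ndarray  # (J,)
    full_model: LassoModel  # full-data fit at lambda_min (standardized scale)
    full_path: np.ndarray  # (n_grid, J) full-data coefficients along the grid
    full_path_intercepts: np.ndarray
    seed: int | None
    n_splits: int
    holdout_fraction: float

    @property
    def retained_terms(self) -> tuple[str, ...]:
        return self.full_model.active_set


def select_lambda_min(
    mse_mean: np.ndarray, grid: np.ndarray, rtol: float = 0.0
) -> int:
    """Index of the penalty minimizing mean test MSE; ties go to the larger
    (sparser) penalty."""
    best = float(np.min(mse_mean))
    tied = np.nonzero(mse_mean <= best * (1.0 + rtol) + 0.0)[0]
    return int(tied[np.argmax(grid[tied])])


def repeated_holdout_cv(
    design: np.ndarray,
    outcome: np.ndarray,
    names: Sequence[str] | None = None,
    grid: np.ndarray | None = None,
    n_splits: int = DEFAULT_N_SPLITS,
    holdout_fraction: float = DEFAULT_HOLDOUT,
    seed: int = 0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    grid_steps: int = DEFAULT_GRID_STEPS,
    tol: float = 1e-8,
) -> CVResult:
    """Full repeated-holdout protocol for one design/outcome pair.

    The raw design is standardized on the full data to fix the penalty grid
    (0 .. lambda_max in ``grid_steps`` steps); each split re-standardizes on
    its training rows, fits the whole path with warm starts, and scores the
    held-out rows.  Reproducible from ``seed`` (or an explicit ``splits``
    list, which lets several model families share the same split sequence).
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(outcome, dtype=float).ravel()
    n, j = X.shape
    if n != len(y):
        raise ValidationError("design and outcome lengths differ")
    if n < 10:
        raise ValidationError(f"need at least 10 samples, got {n}")
    names = tuple(names) if names is not None else _default_names(j)

    if splits is None:
        splits = make_splits(n, n_splits, holdout_fraction, seed)
    n_splits = len(splits)
    if min(len(tr) for tr, _ in splits) < j + 2:
        raise ValidationError(
            f"training splits of size {min(len(tr) for tr, _ in splits)} are too small "
            f"for {j} predictors (need >= {j + 2})"
        )

    z_full, means_full, sds_full = _standardize_safe(X)
    full_record = StandardizationRecord(means=means_full, sds=sds_full, names=names)
    if grid is None:
        grid = lambda_grid(lambda_max(z_full, y), steps=grid_steps)
    grid = np.asarray(grid, dtype=float)
    n_grid = len(grid)

    mse_split = np.empty((n_splits, n_grid))
    coef_split_path = np.empty((n_splits, n_grid, j))
    for s, (train, test) in enumerate(splits):
        z_tr, mu, sd = _standardize_safe(X[train])
        y_tr = y[train]
        z_te = (X[test] - mu) / sd
        betas, intercepts = lasso_path(z_tr, y_tr, grid, tol=tol)
        preds = intercepts[:, None] + betas @ z_te.T  # (n_grid, n_test)
        mse_split[s] = np.mean((preds - y[test][None, :]) ** 2, axis=1)
        coef_split_path[s] = betas

    mse_mean = mse_split.mean(axis=0)
    mse_se = mse_split.std(axis=0, ddof=1) / np.sqrt(n_splits)
    idx_min = select_lambda_min(mse_mean, grid)
    lam_min = float(grid[idx_min])

    full_path_betas, full_path_icepts = lasso_path(z_full, y, grid, tol=tol)
    full_model = LassoModel(
        beta0=float(full_path_icepts[idx_min]),
        betas=full_path_betas[idx_min].copy(),
        lambda_=lam_min,
        names=names,
        record=full_record,
    )
    mse_all = float(np.mean((y - full_model.predict(z_full)) ** 2))

    coef_at_min = coef_split_path[:, idx_min, :]
    return CVResult(
        names=names,
        lambda_grid=grid,
        mse_split=mse_split,
        mse_test_mean=mse_mean,
        mse_test_se=mse_se,
        lambda_min=lam_min,
        lambda_min_index=idx_min,
        mse_all=mse_all,
        coef_split=coef_at_min,
        coef_mean=coef_at_min.mean(axis=0),
        coef_sd=coef_at_min.std(axis=0, ddof=1),
        full_model=full_model,
        full_path=full_path_betas,
        full_path_intercepts=full_path_icepts,
        seed=seed,
        n_splits=n_splits,
        holdout_fraction=holdout_fraction,
    )


# ---------------------------------------------------------------------------
# reference models
# ---------------------------------------------------------------------------


@dataclass
class ReferenceCV:
    """Repeated-holdout result for a reference model (constant or mean-BR)."""

    model: str  # "constant" | "mean_br"
    mse_split: np.ndarray
    mse_test_mean: float
    mse_test_se: float
    mse_all: float
    full_coef: tuple[float, ...]  # (intercept,) or (intercept, slope)


def fit_reference_models(
    mean_br: np.ndarray,
    outcome: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[ReferenceCV, ReferenceCV]:
    """Constant and one-predictor mean-BR models on a shared split sequence.

    The constant model predicts the training-outcome mean (its full-data MSE
    is the biased sample variance of the outcome); the mean-BR model is an
    ordinary least-squares fit on the mean BR alone.
    """
    x = np.asarray(mean_br, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("mean_br and outcome lengths differ")

    def _ols1(xs, ys):
        # one-predictor least squares; a constant predictor falls back to
        # the intercept-only fit
        if xs.std() <= 1e-12 * max(1.0, abs(xs.mean())):
            return 0.0, float(ys.mean())
        slope, icept = np.polyfit(xs, ys, 1)
        return float(slope), float(icept)

    n_splits = len(splits)
    mse_const = np.empty(n_splits)
    mse_br = np.empty(n_splits)
    for s, (train, test) in enumerate(splits):
        mu = y[train].mean()
        mse_const[s] = np.mean((y[test] - mu) ** 2)
        slope, icept = _ols1(x[train], y[train])
        mse_br[s] = np.mean((y[test] - (icept + slope * x[test])) ** 2)

    const_full = (float(y.mean()),)
    const_all = float(np.mean((y - y.mean()) ** 2))
    slope_f, icept_f = _ols1(x, y)
    br_all = float(np.mean((y - (icept_f + slope_f * x)) ** 2))

    def _ref(model, mse, mse_all, coef):
        return ReferenceCV(
            model=model,
            mse_split=mse,
            mse_test_mean=float(mse.mean()),
            mse_test_se=float(mse.std(ddof=1) / np.sqrt(n_splits)),
            mse_all=mse_all,
            full_coef=coef,
        )

    return (
        _ref("constant", mse_const, const_all, const_full),
        _ref("mean_br", mse_br, br_all, (float(icept_f), float(slope_f))),
    )


# ---------------------------------------------------------------------------
# coefficient stability / significance
# ---------------------------------------------------------------------------


def coefficient_significance(cv_result: CVResult, design: np.ndarray, outcome: np.ndarray):
    """Coefficient stability table with post-selection p-values.

    P-values come from an ordinary least-squares refit restricted to the
    active set of the full-data fit at lambda_min (two-sided t-tests); the CV
    mean/SD of each coefficient is reported alongside.  The p-value method is
    recorded in the returned frame's ``attrs`` because it is a package
    convention, not part of the LASSO objective.
    """
    import pandas as pd
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(outcome, dtype=float).ravel()
    z = cv_result.full_model.record.apply(X) if cv_result.full_model.record else X

    frame = pd.DataFrame(
        {
            "coef_cv_mean": cv_result.coef_mean,
            "coef_cv_sd": cv_result.coef_sd,
            "coef_full": cv_result.full_model.betas,
        },
        index=list(cv_result.names),
    )
    frame["pvalue"] = np.nan
    frame.attrs["pvalue_method"] = "ols_refit_active_set"

    active = [i for i, b in enumerate(cv_result.full_model.betas) if b != 0.0]
    if not active:
        frame.attrs["note"] = "empty active set at lambda_min; no p-values"
        return frame
    ols = sm.OLS(y, sm.add_constant(z[:, active])).fit()
    # guard against exact fits where the t statistic degenerates
    pvals = np.nan_to_num(ols.pvalues[1:], nan=0.0)
    for col, p in zip(active, pvals):
        frame.iloc[col, frame.columns.get_loc("pvalue")] = max(float(p), 5e-324)
    return frame
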