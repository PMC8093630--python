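"""Radiomic feature pre-selection by L1-penalized logistic regression.

Covariates are standardized, an L1-penalized binomial model is fitted along a
decreasing penalty grid (cyclic coordinate descent on the IRLS quadratic
approximation, warm starts, unpenalized intercept), and the penalty is chosen
as the minimizer of the mean leave-one-out cross-validated deviance.  Features
with a nonzero coefficient at the selected penalty survive the reduction.

The objective at penalty lam is (1/n) * binomial negative log-likelihood
+ lam * sum_j |beta_j|.  Standardization inside the solver uses the
n-denominator (population) sd; no one-standard-error rule is applied — the
minimizing penalty is used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _fastfit

__all__ = [
    "LassoPath",
    "LassoLogisticCV",
    "standardize",
    "make_lambda_grid",
    "fit_lasso_logistic_path",
    "select_lambda_loocv",
    "selected_features",
]


@dataclass(frozen=True)
class ScalingRecord:
    """Column means and sds used for standardization (population sd)."""

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.sds + self.means


@dataclass(frozen=True)
class LassoPath:
    """Fitted coefficient path with its LOOCV deviance curve."""

    names: tuple[str, ...]
    lambda_grid: np.ndarray  # decreasing
    intercepts: np.ndarray  # per lambda
    coefficients: np.ndarray  # (n_lambda, p), standardized scale
    cv_deviance: np.ndarray | None = None
    lambda_min: float | None = None

    def coefficients_at(self, lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.lambda_grid - lam)))
        return self.coefficients[idx]


def standardize(table: pd.DataFrame | np.ndarray, ddof: int = 0):
    """Center columns to mean 0 and scale to sd 1 (population sd by default).

    Returns (standardized DataFrame/array, ScalingRecord).  Constant columns
    raise an error naming the offending column.
    """
    df = pd.DataFrame(table)
    X = df.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    bad = [str(c) for c, s in zip(df.columns, sds) if s == 0]
    if bad:
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    record = ScalingRecord(tuple(str(c) for c in df.columns), means, sds)
    out = pd.DataFrame(record.transform(X), columns=df.columns, index=df.index)
    return out, record


def make_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                     min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty grid from the KKT zero-threshold lambda_max down.

    lambda_max = max_j |(1/n) X_j^T (y - ybar)| is the smallest penalty at
    which every coefficient is zero (X standardized).
    """
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


class LassoLogisticCV(BaseEstimator):
    """L1-penalized logistic feature selector with LOOCV-deviance penalty choice.

    Parameters
    ----------
    n_lambda : grid size (log-spaced from lambda_max down).
    lambda_min_ratio : smallest grid value as a fraction of lambda_max.
    lambda_grid : explicit grid (overrides the two above when given).
    tol : coordinate-descent convergence threshold (max coefficient change).

    Fitted attributes
    -----------------
    path_ : :class:`LassoPath` with grid, coefficients, CV curve and lambda_min.
    lambda_min_ : selected penalty.
    coef_, intercept_ : coefficients at lambda_min (standardized scale).
    selected_, support_ : surviving feature names / boolean mask.
    scaling_ : the :class:`ScalingRecord` used internally.
    """

    def __init__(self, n_lambda: int = 100, lambda_min_ratio: float = 1e-3,
                 lambda_grid=None, tol: float = 1e-7):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_grid = lambda_grid
        self.tol = tol

    def fit(self, X, y):
        df = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(df) != len(y):
            raise ValueError("X and y lengths differ")
        if len(df) < 10:
            raise ValueError("need at least 10 subjects")
        if df.isna().any().any() or np.any(~np.isfinite(y)):
            raise ValueError("missing values are not allowed")
        names = tuple(str(c) for c in df.columns)
        Xs_df, self.scaling_ = standardize(df)
        Xs = np.ascontiguousarray(Xs_df.to_numpy(dtype=float))

        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            grid = np.sort(grid)[::-1].copy()
        else:
            grid = make_lambda_grid(Xs, y, self.n_lambda, self.lambda_min_ratio)

        intercepts, coefs, conv = _fastfit.lasso_path(Xs, y, grid, self.tol)
        if not conv.all():
            bad = grid[~conv]
            raise RuntimeError(f"coordinate descent did not converge at lambda={bad}")
        cv_dev = _fastfit.loocv_deviance(np.ascontiguousarray(df.to_numpy(float)), y,
                                         grid, self.tol)
        imin = int(np.argmin(cv_dev))
        self.path_ = LassoPath(names, grid, intercepts, coefs, cv_dev, float(grid[imin]))
        self.lambda_min_ = float(grid[imin])
        self.coef_ = coefs[imin].copy()
        self.intercept_ = float(intercepts[imin])
        self.support_ = self.coef_ != 0
        self.selected_ = tuple(n for n, s in zip(names, self.support_) if s)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X):
        df = pd.DataFrame(X)
        return df.loc[:, list(self.selected_)]

    def get_support(self):
        return self.support_.copy()


def fit_lasso_logistic_path(X, y, grid=None, tol: float = 1e-7) -> LassoPath:
    """Fit the penalized path on pre-standardized X (no CV selection)."""
    Xs = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if grid is None:
        grid = make_lambda_grid(Xs, y)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1].copy()
    intercepts, coefs, conv = _fastfit.lasso_path(Xs, y, grid, tol)
    if not conv.all():
        raise RuntimeError(f"coordinate descent did not converge at lambda={grid[~conv]}")
    names = tuple(str(c) for c in getattr(X, "columns", range(Xs.shape[1])))
    return LassoPath(names, grid, intercepts, coefs)


def select_lambda_loocv(X, y, grid=None, tol: float = 1e-7):
    """Return (lambda_min, cv_deviance) by mean LOOCV held-out deviance."""
    est = LassoLogisticCV(lambda_grid=grid, tol=tol).fit(pd.DataFrame(X), y)
    return est.lambda_min_, est.path_.cv_deviance


def selected_features(path: LassoPath) -> tuple[str, ...]:
    """Names with nonzero coefficient at the selected penalty."""
    if path.lambda_min is None:
        raise ValueError("path has no selected lambda (fit with CV first)")
    coefs = path.coefficients_at(path.lambda_min)
    return tuple(n for n, c in zip(path.names, coefs) if c != 0)
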