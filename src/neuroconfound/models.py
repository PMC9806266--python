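"""l2-penalized linear models with two-stage cross-validated C selection.

One inverse-penalty grid serves both model families: ridge regression
minimizes ``sum (y - Xw - b)^2 + (1/C) ||w||^2`` and l2 logistic regression
maximizes ``loglik - (1/(2C)) ||w||^2`` (the intercept unpenalized in both).
Selection runs 5-fold CV over the coarse decade grid (1e-5 .. 1e5), then an
11-point log-spaced refinement spanning one decade either side of the
coarse optimum; ties break toward the strongest penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import log_loss, mean_squared_error
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["GridSpec", "LinearModelFit", "fit_ridge", "fit_logistic_l2", "select_C"]

COARSE_C_GRID = tuple(10.0**k for k in range(-5, 6))


@dataclass
class GridSpec:
    """Inverse-penalty search grid: coarse decades plus one refinement."""

    coarse: tuple[float, ...] = COARSE_C_GRID
    refine_points: int = 11
    refine_span_decades: float = 1.0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.coarse):
            raise ValueError("all C values must be positive")
        self.coarse = tuple(sorted(self.coarse))

    def refined(self, c_star: float) -> np.ndarray:
        lo = np.log10(c_star) - self.refine_span_decades
        hi = np.log10(c_star) + self.refine_span_decades
        return np.logspace(lo, hi, self.refine_points)


@dataclass
class LinearModelFit:
    """A fitted l2 linear model (regression or classification)."""

    coef: np.ndarray
    intercept: float
    C: float
    task: str
    fold_scores: dict = field(default_factory=dict)
    _estimator: object | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Linear predictions (regression) or P(class 1) (classification)."""
        X = np.asarray(X, dtype=float)
        eta = X @ self.coef + self.intercept
        if self.task == "classification":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def state_arrays(self) -> list[np.ndarray]:
        return [np.atleast_1d(self.coef), np.array([self.intercept, self.C])]


def _check_finite(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in model inputs")
    return X, y


def fit_ridge(X: np.ndarray, y: np.ndarray, C: float) -> LinearModelFit:
    """Closed-form ridge regression with inverse penalty C (alpha = 1/C)."""
    X, y = _check_finite(X, y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if C <= 0:
        raise ValueError("C must be positive")
    est = Ridge(alpha=1.0 / C, solver="cholesky").fit(X, y)
    return LinearModelFit(
        coef=est.coef_.copy(),
        intercept=float(est.intercept_),
        C=float(C),
        task="regression",
        _estimator=est,
    )


def fit_logistic_l2(X: np.ndarray, y: np.ndarray, C: float) -> LinearModelFit:
    """l2-penalized logistic regression; y must contain both classes."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in model inputs")
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class")
    if C <= 0:
        raise ValueError("C must be positive")
    est = LogisticRegression(
        C=C, solver="lbfgs", max_iter=10000, tol=1e-8
    ).fit(X, y)
    return LinearModelFit(
        coef=est.coef_.ravel().copy(),
        intercept=float(est.intercept_[0]),
        C=float(C),
        task="classification",
        _estimator=est,
    )


def _cv_score(X, y, C, task, splits) -> float:
    """Mean held-out MSE (regression) or log-loss (classification)."""
    scores = []
    for tr, va in splits:
        if task == "regression":
            fit = fit_ridge(X[tr], y[tr], C)
            scores.append(mean_squared_error(y[va], fit.predict(X[va])))
        else:
            fit = fit_logistic_l2(X[tr], y[tr], C)
            proba = fit.predict(X[va])
            scores.append(log_loss(y[va], proba, labels=np.unique(y)))
    return float(np.mean(scores))


def select_C(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "regression",
    grid: GridSpec | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, dict]:
    """Two-stage grid search for C by k-fold CV on the training data.

    Stage 1 scans the coarse decade grid; stage 2 scans ``refine_points``
    log-spaced values spanning one decade either side of the stage-1
    optimum.  Ties break to the smallest C (strongest penalty); grids are
    evaluated in ascending order, so the first minimum wins.  Returns the
    selected C and a log of per-C mean CV losses.
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    grid = grid or GridSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"{n} rows is fewer than {folds} folds")

    if task == "classification":
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(X, y))
    else:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(X))

    coarse = np.asarray(grid.coarse)
    coarse_scores = np.array([_cv_score(X, y, c, task, splits) for c in coarse])
    c1 = float(coarse[int(np.argmin(coarse_scores))])

    refined = np.sort(grid.refined(c1))
    refined_scores = np.array([_cv_score(X, y, c, task, splits) for c in refined])
    c2 = float(refined[int(np.argmin(refined_scores))])

    log = {
        "coarse": dict(zip(coarse.tolist(), coarse_scores.tolist())),
        "refined": dict(zip(refined.tolist(), refined_scores.tolist())),
        "stage1_C": c1,
        "selected_C": c2,
    }
    return c2, log
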