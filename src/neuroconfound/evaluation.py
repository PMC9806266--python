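"""Held-out performance metrics and permutation significance.

R-squared follows the holdout definition ``1 - sum (y_i - p_i)^2 /
sum (y_i - ybar)^2`` with ``ybar`` the mean of the *measured* scores in the
evaluated set — it can go negative when the model underperforms the
constant-ybar baseline.  The permutation test shuffles the training target,
refits the entire pipeline, and records held-out metrics; the one-tailed
p-value uses additive smoothing ``(1 + k) / (1 + B)`` so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "PredictionResult",
    "PermutationResult",
    "regression_metrics",
    "classification_metrics",
    "permutation_test",
]

#: direction in which a metric improves: "le" = smaller is better
METRIC_DIRECTIONS = {"mae": "le", "rmse": "le", "r2": "ge", "accuracy": "ge", "auc": "ge"}


@dataclass
class PredictionResult:
    """Held-out predictions with their metrics."""

    y: np.ndarray
    p: np.ndarray
    metrics: dict[str, float]
    task: str = "regression"


def regression_metrics(y: np.ndarray, p: np.ndarray) -> dict[str, float]:
    """MAE, RMSE and holdout R-squared."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("y and p must be 1-D arrays of equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("measured scores have zero variance; R^2 undefined")
    err = y - p
    return {
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "r2": 1.0 - float(np.sum(err**2)) / ss_tot,
    }


def classification_metrics(y: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    """Accuracy at the 0.5 probability threshold, and AUC.

    AUC is the rank statistic: the probability that a random positive
    outranks a random negative, ties counting one half.
    """
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape or y.ndim != 1:
        raise ValueError("y and scores must be 1-D arrays of equal length")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need both classes present; AUC undefined otherwise")
    pred = (scores >= 0.5).astype(float)
    return {
        "accuracy": float(np.mean(pred == y)),
        "auc": float(roc_auc_score(y, scores)),
    }


@dataclass
class PermutationResult:
    """Null distributions and one-tailed p-values of held-out metrics."""

    B: int
    observed: dict[str, float]
    null: dict[str, np.ndarray]
    p_values: dict[str, float]
    seed: int
    directions: dict[str, str] = field(default_factory=dict)


def permutation_test(
    evaluate_fn: Callable[[np.ndarray], dict[str, float]],
    y_train: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    directions: dict[str, str] | None = None,
) -> PermutationResult:
    """Permutation significance of held-out pipeline performance.

    ``evaluate_fn`` must refit the *entire* pipeline (correction,
    processing, C selection, stacking if present) on the training target it
    receives and return held-out metrics.  The observed metrics come from
    the unpermuted target; each of the B null draws shuffles the training
    target before the pipeline sees it.  One-tailed p per metric:
    ``(1 + #{null at least as good}) / (B + 1)``, where "as good" respects
    the metric's direction (<= for errors, >= for scores).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    directions = directions or METRIC_DIRECTIONS
    y_train = np.asarray(y_train)
    observed = evaluate_fn(y_train)

    rng = np.random.default_rng(seed)
    null: dict[str, list[float]] = {k: [] for k in observed}
    for _ in range(B):
        perm = rng.permutation(y_train)
        m = evaluate_fn(perm)
        for k in null:
            null[k].append(m[k])

    p_values = {}
    null_arrays = {k: np.asarray(v) for k, v in null.items()}
    for k, obs in observed.items():
        direction = directions.get(k, "ge")
        if direction == "le":
            better = int(np.sum(null_arrays[k] <= obs))
        else:
            better = int(np.sum(null_arrays[k] >= obs))
        p_values[k] = (1 + better) / (B + 1)

    return PermutationResult(
        B=B,
        observed=observed,
        null=null_arrays,
        p_values=p_values,
        seed=seed,
        directions=dict(directions),
    )
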