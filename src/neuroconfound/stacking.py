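"""Pre-validated multimodal stacking.

First-level pipelines are fit within a 10-fold cross-validation on the
training set; their out-of-fold (OOF) predictions — never produced by a
model that saw the subject's fold — become the regressors of an
unregularized second-level model (pre-validation).  At test time the
first-level models are refit on the full training set and the second-level
model combines their test predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .confounds import GroupDemeaner
from .evaluation import PredictionResult, classification_metrics, regression_metrics
from .pipeline import PredictionPipeline
from .preprocessing import state_hash

logger = logging.getLogger(__name__)

__all__ = ["OofMatrix", "prevalidated_features", "fit_stack", "MultimodalPipeline"]


@dataclass
class OofMatrix:
    """Training subjects x pipelines matrix of out-of-fold predictions."""

    matrix: np.ndarray
    fold_assignment: np.ndarray
    pipeline_names: list[str]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.matrix, columns=self.pipeline_names)
        df["fold"] = self.fold_assignment
        return df


def _make_folds(y, folds, seed, task):
    if task == "classification":
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros_like(y), y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros_like(y)))


def prevalidated_features(
    pipeline_factories: dict[str, Callable[[], PredictionPipeline]],
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    group: np.ndarray | None = None,
    covariate: np.ndarray | None = None,
    task: str = "regression",
) -> OofMatrix:
    """Out-of-fold predictions of every first-level pipeline.

    One seeded fold assignment is shared across pipelines so the OOF
    columns are comparable.  Within each fold, each pipeline refits its
    whole stack of state (correction, winsor/scale/PCA, C selection) on
    the other folds.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    names = list(pipeline_factories)
    n = len(y)
    for name in names:
        if blocks[name].shape[0] != n:
            raise ValueError(f"block {name!r} is not row-aligned with y")
    splits = _make_folds(np.asarray(y), folds, seed, task)
    fold_assignment = np.empty(n, dtype=int)
    oof = np.empty((n, len(names)))
    for k, (tr, va) in enumerate(splits):
        fold_assignment[va] = k
        for j, name in enumerate(names):
            X = blocks[name]
            pipe = pipeline_factories[name]()
            pipe.fit(
                X[tr],
                np.asarray(y)[tr],
                group=None if group is None else group[tr],
                covariate=None if covariate is None else covariate[tr],
            )
            oof[va, j] = pipe.predict(
                X[va],
                group=None if group is None else group[va],
                covariate=None if covariate is None else covariate[va],
            )
    return OofMatrix(matrix=oof, fold_assignment=fold_assignment, pipeline_names=names)


def fit_stack(oof: OofMatrix, y: np.ndarray, task: str = "regression"):
    """Unregularized second-level model on the OOF columns.

    Linear regression for a continuous target (minimum-norm solution on a
    rank-deficient OOF matrix, which is logged), unpenalized logistic
    regression for a binary one.
    """
    X = oof.matrix
    if X.shape[1] < 1:
        raise ValueError("OOF matrix must have at least one column")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        logger.warning("rank-deficient OOF matrix; minimum-norm solution used")
    if task == "regression":
        return LinearRegression().fit(X, np.asarray(y, dtype=float))
    return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000).fit(
        X, np.asarray(y)
    )


class MultimodalPipeline:
    """Stacked multimodal model over named first-level pipelines.

    For regression with group demeaning, a target corrector is fit on the
    full training set; the second-level model and all evaluation operate on
    that corrected target (per-fold first-level fits carry their own
    corrections internally).
    """

    def __init__(
        self,
        pipeline_factories: dict[str, Callable[[], PredictionPipeline]],
        task: str = "regression",
        folds: int = 10,
        seed: int = 0,
        target_correction: str | None = None,
    ):
        if task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        self.pipeline_factories = dict(pipeline_factories)
        self.task = task
        self.folds = folds
        self.seed = seed
        self.target_correction = target_correction
        self.first_level_: dict[str, PredictionPipeline] = {}
        self.stack_ = None
        self.oof_: OofMatrix | None = None
        self.target_demeaner_: GroupDemeaner | None = None
        self.classes_: np.ndarray | None = None

    def _corrected_y(self, y, group):
        if self.target_correction == "demean_by_group" and self.task == "regression":
            return self.target_demeaner_.transform_y(y, group)
        return np.asarray(y, dtype=float)

    def _encode_y(self, y):
        if self.task == "regression":
            return np.asarray(y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("classification target must have exactly 2 classes")
        return (np.asarray(y) == self.classes_[1]).astype(float)

    def fit(self, blocks, y, group=None, covariate=None) -> "MultimodalPipeline":
        yb = self._encode_y(y)
        if self.target_correction == "demean_by_group" and self.task == "regression":
            if group is None:
                raise ValueError("demean_by_group requires group labels")
            self.target_demeaner_ = GroupDemeaner().fit(
                np.zeros((len(yb), 0)), yb, group
            )
        self.oof_ = prevalidated_features(
            self.pipeline_factories,
            blocks,
            yb,
            folds=self.folds,
            seed=self.seed,
            group=group,
            covariate=covariate,
            task=self.task,
        )
        y_stack = self._corrected_y(yb, group)
        self.stack_ = fit_stack(self.oof_, y_stack, task=self.task)
        for name, factory in self.pipeline_factories.items():
            pipe = factory()
            pipe.fit(blocks[name], yb, group=group, covariate=covariate)
            self.first_level_[name] = pipe
        return self

    def _first_level_matrix(self, blocks, group, covariate) -> np.ndarray:
        cols = []
        for name in self.oof_.pipeline_names:
            if name not in blocks:
                raise ValueError(f"block {name!r} missing at prediction time")
            cols.append(
                self.first_level_[name].predict(
                    blocks[name], group=group, covariate=covariate
                )
            )
        return np.column_stack(cols)

    def predict(self, blocks, group=None, covariate=None) -> np.ndarray:
        if self.stack_ is None:
            raise RuntimeError("fit before predict")
        F = self._first_level_matrix(blocks, group, covariate)
        if self.task == "regression":
            return self.stack_.predict(F)
        return self.stack_.predict_proba(F)[:, 1]

    def transform_target(self, y, group=None) -> np.ndarray:
        if self.task == "classification":
            return (np.asarray(y) == self.classes_[1]).astype(float)
        return self._corrected_y(np.asarray(y, dtype=float), group)

    def evaluate(self, blocks_test, y_test, group=None, covariate=None) -> PredictionResult:
        p = self.predict(blocks_test, group=group, covariate=covariate)
        yt = self.transform_target(y_test, group=group)
        if self.task == "regression":
            metrics = regression_metrics(yt, p)
        else:
            metrics = classification_metrics(yt, p)
        return PredictionResult(y=yt, p=p, metrics=metrics, task=self.task)

    def state_arrays(self) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        for name in sorted(self.first_level_):
            arrays += self.first_level_[name].state_arrays()
        if self.target_demeaner_ is not None:
            arrays += self.target_demeaner_.state_arrays()
        if self.stack_ is not None:
            coef = getattr(self.stack_, "coef_", None)
            intercept = getattr(self.stack_, "intercept_", None)
            if coef is not None:
                arrays += [np.atleast_1d(coef).ravel(), np.atleast_1d(intercept)]
        return arrays

    def state_hash(self) -> str:
        return state_hash(self.state_arrays())
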