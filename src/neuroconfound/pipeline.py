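"""First-level prediction pipeline: correction -> processing -> l2 model.

A :class:`PredictionPipeline` bundles an optional train-fitted confound
correction (group demeaning or covariate residualization), the winsorize /
scale / PCA processor, and an l2 model whose inverse penalty C is chosen by
two-stage nested cross-validation (or frozen via ``fixed_C``).  Every fit
step sees training rows only; the fitted state then applies unchanged to
test rows.
"""

from __future__ import annotations

import numpy as np

from .confounds import GroupDemeaner, Residualizer
from .evaluation import PredictionResult, classification_metrics, regression_metrics
from .models import GridSpec, fit_logistic_l2, fit_ridge, select_C
from .preprocessing import FeatureProcessor, state_hash

__all__ = ["PredictionPipeline"]

_CORRECTIONS = (None, "demean_by_group", "residualize_on_covariate")


class PredictionPipeline:
    """End-to-end first-level pipeline for one feature block.

    Parameters
    ----------
    task:
        "regression" (ridge) or "classification" (l2 logistic).
    correction:
        None, "demean_by_group" (removes group means from features and,
        for regression, the target) or "residualize_on_covariate"
        (removes a continuous covariate from the features only).
    use_pca:
        "auto" applies PCA to n_train - 1 components iff p > n_train.
    fixed_C:
        Skip C selection and use this inverse penalty (used by bootstrap
        refits, where hyperparameters stay frozen at the full-train value).
    """

    def __init__(
        self,
        task: str = "regression",
        correction: str | None = None,
        use_pca: bool | str = "auto",
        grid: GridSpec | None = None,
        cv_folds: int = 5,
        fixed_C: float | None = None,
        seed: int = 0,
    ):
        if task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if correction not in _CORRECTIONS:
            raise ValueError(f"correction must be one of {_CORRECTIONS}")
        if correction == "demean_by_group" and task == "classification":
            raise ValueError(
                "group demeaning targets a continuous outcome; use "
                "residualize_on_covariate for classification"
            )
        self.task = task
        self.correction = correction
        self.use_pca = use_pca
        self.grid = grid or GridSpec()
        self.cv_folds = cv_folds
        self.fixed_C = fixed_C
        self.seed = seed
        self.corrector_ = None
        self.processor_: FeatureProcessor | None = None
        self.model_ = None
        self.selection_log_: dict | None = None
        self.classes_: np.ndarray | None = None

    def clone(self, **overrides) -> "PredictionPipeline":
        """Fresh unfitted pipeline with the same configuration."""
        params = dict(
            task=self.task,
            correction=self.correction,
            use_pca=self.use_pca,
            grid=self.grid,
            cv_folds=self.cv_folds,
            fixed_C=self.fixed_C,
            seed=self.seed,
        )
        params.update(overrides)
        return PredictionPipeline(**params)

    # -- correction plumbing -------------------------------------------------

    def _fit_correction(self, X, y, group, covariate):
        if self.correction is None:
            return X, y
        if self.correction == "demean_by_group":
            if group is None:
                raise ValueError("demean_by_group requires group labels")
            self.corrector_ = GroupDemeaner().fit(
                X, y if self.task == "regression" else None, group
            )
            Xc = self.corrector_.transform_X(X, group)
            yc = self.corrector_.transform_y(y, group) if self.task == "regression" else y
            return Xc, yc
        if covariate is None:
            raise ValueError("residualize_on_covariate requires a covariate")
        self.corrector_ = Residualizer().fit(X, covariate)
        return self.corrector_.transform(X, covariate), y

    def _apply_correction_X(self, X, group, covariate):
        if self.correction is None:
            return X
        if self.correction == "demean_by_group":
            if group is None:
                raise ValueError("demean_by_group requires group labels")
            return self.corrector_.transform_X(X, group)
        if covariate is None:
            raise ValueError("residualize_on_covariate requires a covariate")
        return self.corrector_.transform(X, covariate)

    def transform_target(self, y, group=None) -> np.ndarray:
        """Target in the corrected space the model was trained in."""
        if self.correction == "demean_by_group" and self.task == "regression":
            return self.corrector_.transform_y(y, group)
        return np.asarray(y, dtype=float)

    # -- fitting and prediction ----------------------------------------------

    def _encode_y(self, y):
        if self.task == "regression":
            return np.asarray(y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("classification target must have exactly 2 classes")
        return (np.asarray(y) == self.classes_[1]).astype(float)

    def fit(self, X, y, group=None, covariate=None) -> "PredictionPipeline":
        X = np.asarray(X, dtype=float)
        yb = self._encode_y(y)
        Xc, yc = self._fit_correction(X, yb, group, covariate)
        self.processor_ = FeatureProcessor(use_pca=self.use_pca).fit(Xc)
        Z = self.processor_.transform(Xc)
        if self.fixed_C is not None:
            C = float(self.fixed_C)
            self.selection_log_ = {"selected_C": C, "fixed": True}
        else:
            C, self.selection_log_ = select_C(
                Z, yc, task=self.task, grid=self.grid, folds=self.cv_folds,
                seed=self.seed,
            )
        if self.task == "regression":
            self.model_ = fit_ridge(Z, yc, C)
        else:
            self.model_ = fit_logistic_l2(Z, yc, C)
        return self

    def predict(self, X, group=None, covariate=None) -> np.ndarray:
        """Corrected-space predictions (scores or P(class 1))."""
        if self.model_ is None:
            raise RuntimeError("fit before predict")
        Xc = self._apply_correction_X(np.asarray(X, dtype=float), group, covariate)
        return self.model_.predict(self.processor_.transform(Xc))

    def evaluate(self, X_test, y_test, group=None, covariate=None) -> PredictionResult:
        """Held-out metrics against the (corrected, where applicable) target."""
        p = self.predict(X_test, group=group, covariate=covariate)
        if self.task == "regression":
            yt = self.transform_target(y_test, group=group)
            metrics = regression_metrics(yt, p)
        else:
            yt = (np.asarray(y_test) == self.classes_[1]).astype(float)
            metrics = classification_metrics(yt, p)
        return PredictionResult(y=np.asarray(yt, dtype=float), p=p, metrics=metrics,
                                task=self.task)

    # -- introspection -------------------------------------------------------

    @property
    def selected_C(self) -> float:
        if self.model_ is None:
            raise RuntimeError("fit before selected_C")
        return self.model_.C

    def feature_coefficients(self) -> np.ndarray:
        """Model coefficients mapped back to the standardized feature space."""
        if self.model_ is None:
            raise RuntimeError("fit before feature_coefficients")
        return self.processor_.feature_space_coefficients(self.model_.coef)

    def state_arrays(self) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        if self.corrector_ is not None:
            arrays += self.corrector_.state_arrays()
        if self.processor_ is not None:
            arrays += self.processor_.state_arrays()
        if self.model_ is not None:
            arrays += self.model_.state_arrays()
        return arrays

    def state_hash(self) -> str:
        """Fingerprint of every fitted parameter (leakage audits)."""
        return state_hash(self.state_arrays())
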