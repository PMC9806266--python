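"""Train-fitted confound correction.

Two corrections, both with parameters estimated on training rows only and
then applied unchanged to test rows:

- group demeaning: subtract each sample's own group's training mean from
  every feature (and, for a continuous target, from the target).  For a
  binary group this is exactly regression on the group indicator.
- residualization: per feature, regress out a continuous covariate with a
  simple linear fit and keep the residuals.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GroupDemeaner", "Residualizer"]


class GroupDemeaner:
    """Remove group-specific training means from features and target."""

    def __init__(self):
        self.groups_: np.ndarray | None = None
        self.feature_means_: dict | None = None
        self.target_means_: dict | None = None

    def fit(self, X: np.ndarray, y: np.ndarray | None, group: np.ndarray) -> "GroupDemeaner":
        X = np.asarray(X, dtype=float)
        group = np.asarray(group)
        self.groups_ = np.unique(group)
        self.feature_means_ = {}
        self.target_means_ = {}
        for g in self.groups_:
            mask = group == g
            self.feature_means_[g] = X[mask].mean(axis=0)
            if y is not None:
                self.target_means_[g] = float(np.asarray(y, dtype=float)[mask].mean())
        return self

    def _check(self, group: np.ndarray) -> None:
        if self.feature_means_ is None:
            raise RuntimeError("fit before transform")
        unseen = set(np.unique(group)) - set(self.groups_.tolist())
        if unseen:
            raise ValueError(f"group(s) {sorted(unseen)} were not present in training")

    def transform_X(self, X: np.ndarray, group: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        group = np.asarray(group)
        self._check(group)
        for g in self.groups_:
            X[group == g] -= self.feature_means_[g]
        return X

    def transform_y(self, y: np.ndarray, group: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float).copy()
        group = np.asarray(group)
        self._check(group)
        if not self.target_means_:
            raise RuntimeError("demeaner was fitted without a target")
        for g in self.groups_:
            y[group == g] -= self.target_means_[g]
        return y

    def transform(
        self, X: np.ndarray, y: np.ndarray | None, group: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray | None]:
        Xc = self.transform_X(X, group)
        yc = self.transform_y(y, group) if y is not None else None
        return Xc, yc

    def state_arrays(self) -> list[np.ndarray]:
        if self.feature_means_ is None:
            return []
        arrays = [self.feature_means_[g] for g in self.groups_]
        if self.target_means_:
            arrays.append(np.array([self.target_means_[g] for g in self.groups_]))
        return arrays


class Residualizer:
    """Per-feature residuals of a linear fit on one continuous covariate."""

    def __init__(self):
        self.intercept_: np.ndarray | None = None
        self.slope_: np.ndarray | None = None

    def fit(self, X: np.ndarray, covariate: np.ndarray) -> "Residualizer":
        X = np.asarray(X, dtype=float)
        c = np.asarray(covariate, dtype=float)
        var = c.var()
        if var == 0.0:
            raise ValueError("covariate has zero variance on the training rows")
        c_centered = c - c.mean()
        self.slope_ = (c_centered @ X) / (c_centered @ c_centered)
        self.intercept_ = X.mean(axis=0) - self.slope_ * c.mean()
        if not np.all(np.isfinite(self.slope_)):
            raise ValueError("non-finite residualizer slope")
        return self

    def transform(self, X: np.ndarray, covariate: np.ndarray) -> np.ndarray:
        if self.slope_ is None:
            raise RuntimeError("fit before transform")
        X = np.asarray(X, dtype=float)
        c = np.asarray(covariate, dtype=float)
        return X - (self.intercept_ + np.outer(c, self.slope_))

    def state_arrays(self) -> list[np.ndarray]:
        if self.slope_ is None:
            return []
        return [self.intercept_, self.slope_]
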