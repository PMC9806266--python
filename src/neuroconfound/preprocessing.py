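"""Train-fit / test-apply feature processing: winsorize, scale, PCA.

Every fit step reads training rows only; the fitted state is then applied
unchanged to test rows.  Winsorization clamps to mean +/- 3 SD, scaling
centers and divides by the population SD, and PCA (used when features
outnumber training subjects) reduces to at most n_train - 1 uncorrelated
components via SVD.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["Winsorizer", "Scaler", "PcaReducer", "FeatureProcessor", "state_hash"]


def state_hash(arrays: list[np.ndarray]) -> str:
    """SHA-256 over the bytes of a list of arrays (a FitState fingerprint)."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


class Winsorizer:
    """Clamp features to training mean +/- 3 SD (population SD)."""

    def __init__(self, n_sd: float = 3.0):
        self.n_sd = n_sd
        self.lower_: np.ndarray | None = None
        self.upper_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Winsorizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("winsorizer needs at least 2 training rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # ddof=0: population convention
        self.lower_ = mean - self.n_sd * sd
        self.upper_ = mean + self.n_sd * sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lower_ is None:
            raise RuntimeError("fit before transform")
        return np.clip(np.asarray(X, dtype=float), self.lower_, self.upper_)

    def state_arrays(self) -> list[np.ndarray]:
        return [self.lower_, self.upper_] if self.lower_ is not None else []


class Scaler:
    """Center to training mean, scale to unit population SD.

    Zero-variance features are centered only (scale 1) and logged, so a
    constant column cannot produce NaNs downstream.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.zero_variance_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("scaler needs at least 2 training rows")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.zero_variance_ = sd == 0.0
        if self.zero_variance_.any():
            k = int(self.zero_variance_.sum())
            logger.warning("%d zero-variance feature(s); centering only", k)
        self.scale_ = np.where(self.zero_variance_, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("fit before transform")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def state_arrays(self) -> list[np.ndarray]:
        if self.mean_ is None:
            return []
        return [self.mean_, self.scale_]


class PcaReducer:
    """PCA via SVD with a deterministic sign convention.

    Each component's largest-absolute loading is made positive so that
    back-projected coefficient maps are reproducible across runs.
    ``inverse_map`` is the linear pullback ``loadings^T w``: a model trained
    on scores makes identical predictions when its coefficients are mapped
    into (centered) feature space.
    """

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = n_components
        self.components_: np.ndarray | None = None
        self.mean_: np.ndarray | None = None
        self.explained_variance_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "PcaReducer":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"k={self.n_components} exceeds min(n-1, p)={min(n - 1, p)}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        comps = pca.components_
        # sign convention: dominant loading positive, per component
        flip = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comps * flip[:, None]
        self.mean_ = pca.mean_
        self.explained_variance_ = pca.explained_variance_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("fit before transform")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def inverse_map(self, w: np.ndarray) -> np.ndarray:
        """Pull score-space coefficients back to original feature space."""
        if self.components_ is None:
            raise RuntimeError("fit before inverse_map")
        return self.components_.T @ np.asarray(w, dtype=float)

    def state_arrays(self) -> list[np.ndarray]:
        if self.components_ is None:
            return []
        return [self.components_, self.mean_, self.explained_variance_]


@dataclass
class _ProcessorState:
    used_pca: bool
    n_train: int


class FeatureProcessor:
    """Winsorize -> scale -> (PCA iff features exceed training rows).

    ``use_pca='auto'`` applies PCA only when p > n_train, reducing to
    n_train - 1 components; True/False force the choice.
    """

    def __init__(self, use_pca: bool | str = "auto", n_components: int | None = None):
        if use_pca not in (True, False, "auto"):
            raise ValueError("use_pca must be True, False, or 'auto'")
        self.use_pca = use_pca
        self.n_components = n_components
        self.winsorizer_ = Winsorizer()
        self.scaler_ = Scaler()
        self.pca_: PcaReducer | None = None
        self.state_: _ProcessorState | None = None

    def fit(self, X_train: np.ndarray) -> "FeatureProcessor":
        X_train = np.asarray(X_train, dtype=float)
        n, p = X_train.shape
        Xw = self.winsorizer_.fit(X_train).transform(X_train)
        Xs = self.scaler_.fit(Xw).transform(Xw)
        apply_pca = self.use_pca if self.use_pca != "auto" else p > n
        if apply_pca:
            k = self.n_components if self.n_components is not None else min(n - 1, p)
            self.pca_ = PcaReducer(k).fit(Xs)
        else:
            self.pca_ = None
        self.state_ = _ProcessorState(used_pca=bool(apply_pca), n_train=n)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.state_ is None:
            raise RuntimeError("fit before transform")
        Xs = self.scaler_.transform(self.winsorizer_.transform(X))
        return self.pca_.transform(Xs) if self.pca_ is not None else Xs

    def feature_space_coefficients(self, w: np.ndarray) -> np.ndarray:
        """Model coefficients mapped back onto the standardized features.

        When PCA was applied this is the inverse PCA transform of the
        score-space coefficients; otherwise the coefficients already live
        in (standardized) feature space.
        """
        if self.state_ is None:
            raise RuntimeError("fit before feature_space_coefficients")
        return self.pca_.inverse_map(w) if self.pca_ is not None else np.asarray(w)

    def state_arrays(self) -> list[np.ndarray]:
        arrays = self.winsorizer_.state_arrays() + self.scaler_.state_arrays()
        if self.pca_ is not None:
            arrays += self.pca_.state_arrays()
        return arrays

    def state_hash(self) -> str:
        return state_hash(self.state_arrays())
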