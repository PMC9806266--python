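"""Tangent-space functional connectivity with a training-only reference.

Each subject's region-by-region covariance is projected onto the tangent
space of the SPD manifold at a group reference matrix: the matrix logarithm
of ``ref^(-1/2) C ref^(-1/2)``.  The reference is the affine-invariant
geometric mean of the training covariances (arithmetic mean available as an
option) and is fitted on training subjects only.  The strict lower triangle
of the tangent matrix, vectorized row-major, gives r(r-1)/2 features —
7,381 for a 122-region parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.covariance import LedoitWolf

from .synthetic import FeatureBlock, TimeseriesSet

__all__ = [
    "bandpass",
    "shrinkage_covariance",
    "geometric_mean",
    "tangent_embed",
    "connectivity_features",
    "TangentReference",
    "TangentConnectivity",
]

_SYM_TOL = 1e-10


def bandpass(ts: np.ndarray, low: float, high: float, dt: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a regions x timepoints array.

    An order-5 Butterworth filter is applied forward-backward (zero phase)
    along the time axis.  Defaults elsewhere use the 0.008-0.100 Hz band at
    a 0.72 s sampling interval.
    """
    nyquist = 0.5 / dt
    if not 0.0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyquist} Hz")
    sos = signal.butter(5, [low, high], btype="bandpass", fs=1.0 / dt, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=-1)


def shrinkage_covariance(ts: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrunk covariance of a regions x timepoints array.

    Shrinkage toward the scaled identity keeps the estimate positive
    definite even when timepoints are comparable to (or fewer than) regions.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("need a 2-D regions x timepoints array with >= 2 timepoints")
    cov = LedoitWolf(assume_centered=False).fit(ts.T).covariance_
    return 0.5 * (cov + cov.T)


def _eigh_checked(mat: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    sym_err = np.max(np.abs(mat - mat.T)) if mat.size else 0.0
    if sym_err > 1e-8:
        raise ValueError(f"{what} is not symmetric (max asymmetry {sym_err:.2e})")
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    if vals.min() <= 0:
        raise ValueError(f"{what} is not positive definite (min eig {vals.min():.2e})")
    return vals, vecs


def _spd_power(mat: np.ndarray, power: float, what: str = "matrix") -> np.ndarray:
    vals, vecs = _eigh_checked(mat, what)
    return (vecs * vals**power) @ vecs.T


def _spd_log(mat: np.ndarray, what: str = "matrix") -> np.ndarray:
    vals, vecs = _eigh_checked(mat, what)
    return (vecs * np.log(vals)) @ vecs.T


def _sym_exp(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    return (vecs * np.exp(vals)) @ vecs.T


@dataclass
class TangentReference:
    """Group reference covariance with its whitening factor."""

    covariance: np.ndarray
    whitener: np.ndarray  # covariance**(-1/2)
    iteration_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        asym = np.max(np.abs(self.covariance - self.covariance.T))
        if asym > _SYM_TOL:
            raise ValueError(f"reference asymmetry {asym:.2e} exceeds {_SYM_TOL}")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("reference covariance must be positive definite")

    @property
    def n_regions(self) -> int:
        return self.covariance.shape[0]


def geometric_mean(
    covs: list[np.ndarray], tol: float = 1e-6, max_iter: int = 50
) -> TangentReference:
    """Affine-invariant geometric (Karcher) mean of SPD matrices.

    Fixed-point iteration started at the arithmetic mean: at each step the
    matrices are whitened by the current estimate, their logs averaged, and
    the estimate moved along the resulting tangent vector.  Convergence is
    declared when the Frobenius norm of the tangent-space mean falls below
    ``tol``.
    """
    if not covs:
        raise ValueError("need at least one covariance matrix")
    shapes = {c.shape for c in covs}
    if len(shapes) != 1:
        raise ValueError("all covariance matrices must share one shape")
    for i, c in enumerate(covs):
        _eigh_checked(c, f"covariance {i}")

    g = np.mean(covs, axis=0)
    log: list[float] = []
    for _ in range(max_iter):
        g_isqrt = _spd_power(g, -0.5, "geometric-mean iterate")
        g_sqrt = _spd_power(g, 0.5, "geometric-mean iterate")
        tangent_mean = np.mean([_spd_log(g_isqrt @ c @ g_isqrt) for c in covs], axis=0)
        step = float(np.linalg.norm(tangent_mean, ord="fro"))
        log.append(step)
        if step < tol:
            return TangentReference(
                covariance=0.5 * (g + g.T), whitener=g_isqrt, iteration_log=log
            )
        g = g_sqrt @ _sym_exp(tangent_mean) @ g_sqrt
        g = 0.5 * (g + g.T)
    raise RuntimeError(
        f"geometric mean did not converge in {max_iter} iterations; "
        f"step norms: {log}"
    )


def arithmetic_mean(covs: list[np.ndarray]) -> TangentReference:
    """Arithmetic group mean as an alternative tangent reference."""
    if not covs:
        raise ValueError("need at least one covariance matrix")
    g = np.mean(covs, axis=0)
    g = 0.5 * (g + g.T)
    return TangentReference(
        covariance=g, whitener=_spd_power(g, -0.5, "arithmetic mean"), iteration_log=[]
    )


def tangent_embed(cov: np.ndarray, ref: TangentReference) -> np.ndarray:
    """Project one SPD covariance onto the tangent space at ``ref``.

    Returns the strict lower triangle of ``logm(W C W)`` (W the reference
    whitener), vectorized in row-major order: r(r-1)/2 features.
    """
    if cov.shape != ref.covariance.shape:
        raise ValueError("covariance and reference shapes differ")
    w = ref.whitener
    logm = _spd_log(w @ cov @ w, "whitened covariance")
    r = logm.shape[0]
    rows, cols = np.tril_indices(r, k=-1)
    return logm[rows, cols]


def connectivity_features(runs: list[np.ndarray], ref: TangentReference) -> np.ndarray:
    """Per-run tangent embeddings averaged elementwise across runs."""
    if len(runs) == 0:
        raise ValueError("need at least one run")
    return np.mean([tangent_embed(shrinkage_covariance(r), ref) for r in runs], axis=0)


class TangentConnectivity:
    """Train-fitted tangent connectivity extractor.

    ``fit`` band-passes every training run, estimates per-run shrinkage
    covariances and computes the group reference from training subjects
    only; ``transform`` projects any subject (train or test) without
    touching the reference.
    """

    def __init__(
        self,
        low: float = 0.008,
        high: float = 0.100,
        dt: float = 0.72,
        mean_type: str = "geometric",
        tol: float = 1e-6,
        max_iter: int = 50,
    ):
        if mean_type not in ("geometric", "arithmetic"):
            raise ValueError("mean_type must be 'geometric' or 'arithmetic'")
        self.low = low
        self.high = high
        self.dt = dt
        self.mean_type = mean_type
        self.tol = tol
        self.max_iter = max_iter
        self.reference_: TangentReference | None = None

    def _run_cov(self, run: np.ndarray) -> np.ndarray:
        return shrinkage_covariance(bandpass(run, self.low, self.high, self.dt))

    def fit(self, train_runs: list[list[np.ndarray]]) -> "TangentConnectivity":
        covs = [self._run_cov(run) for subject in train_runs for run in subject]
        if self.mean_type == "geometric":
            self.reference_ = geometric_mean(covs, tol=self.tol, max_iter=self.max_iter)
        else:
            self.reference_ = arithmetic_mean(covs)
        return self

    def transform(self, subject_runs: list[list[np.ndarray]]) -> np.ndarray:
        if self.reference_ is None:
            raise RuntimeError("fit must be called before transform")
        ref = self.reference_
        rows = [
            np.mean([tangent_embed(self._run_cov(r), ref) for r in runs], axis=0)
            for runs in subject_runs
        ]
        return np.vstack(rows)

    def feature_labels(self) -> list[str]:
        if self.reference_ is None:
            raise RuntimeError("fit must be called before feature_labels")
        r = self.reference_.n_regions
        rows, cols = np.tril_indices(r, k=-1)
        return [f"conn_{i:03d}_{j:03d}" for i, j in zip(rows, cols)]

    def state_arrays(self) -> list[np.ndarray]:
        if self.reference_ is None:
            return []
        return [self.reference_.covariance, self.reference_.whitener]


def connectivity_block(
    extractor: TangentConnectivity,
    ts: TimeseriesSet,
    subject_ids,
    name: str = "rs",
) -> FeatureBlock:
    """Project subjects through a fitted extractor into a FeatureBlock."""
    mat = extractor.transform(ts.for_subjects(subject_ids))
    return FeatureBlock(name, mat, extractor.feature_labels())
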