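"""Bootstrap coefficient inference in original feature space, with FDR.

The training set is resampled with replacement B times; the full pipeline
(correction, winsorize/scale/PCA, model with the inverse penalty frozen at
the full-train selection) is refit per replicate and the model coefficients
are mapped back to feature space (inverse PCA where applied).  Per feature,
Z = bootstrap mean / bootstrap SD, two-tailed p from the standard normal,
and Benjamini-Hochberg control at level q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pipeline import PredictionPipeline

__all__ = [
    "CoefficientInference",
    "bootstrap_coefficients",
    "bh_fdr",
    "compare_coefficients_spearman",
]


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def compare_coefficients_spearman(coef_a: np.ndarray, coef_b: np.ndarray) -> float:
    """Spearman rank correlation of two full coefficient vectors."""
    a = np.asarray(coef_a, dtype=float)
    b = np.asarray(coef_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


@dataclass
class CoefficientInference:
    """Per-feature bootstrap summary with BH-adjusted significance."""

    feature_labels: list[str]
    boot_mean: np.ndarray
    boot_sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    zero_sd: np.ndarray
    B: int
    q: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_labels,
                "boot_mean": self.boot_mean,
                "boot_sd": self.boot_sd,
                "z": self.z,
                "p": self.p,
                "significant": self.significant,
            }
        )


def bootstrap_coefficients(
    pipeline_factory: Callable[..., PredictionPipeline],
    X: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    q: float = 0.05,
    group: np.ndarray | None = None,
    covariate: np.ndarray | None = None,
    feature_labels: list[str] | None = None,
    max_redraws: int = 100,
) -> CoefficientInference:
    """Bootstrap-Z inference for one first-level pipeline.

    The pipeline is first fit to the full training set to select C; each
    replicate then refits processing and model on a with-replacement
    resample with C frozen.  Degenerate resamples (a single class, or a
    zero-variance target) are redrawn.  Features with zero bootstrap SD get
    p = 1 and are flagged.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)

    full = pipeline_factory()
    full.fit(X, y, group=group, covariate=covariate)
    c_star = full.selected_C

    rng = np.random.default_rng(seed)
    coefs = []
    for _ in range(B):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if full.task == "classification" and len(np.unique(yb)) < 2:
                continue
            if full.task == "regression" and np.ptp(np.asarray(yb, dtype=float)) == 0:
                continue
            break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        pipe = pipeline_factory(fixed_C=c_star)
        pipe.fit(
            X[idx],
            yb,
            group=None if group is None else group[idx],
            covariate=None if covariate is None else covariate[idx],
        )
        coefs.append(pipe.feature_coefficients())

    coefs = np.asarray(coefs)
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    zero_sd = sd == 0.0
    z = np.zeros_like(mean)
    np.divide(mean, sd, out=z, where=~zero_sd)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[zero_sd] = 1.0
    significant, _ = bh_fdr(p, q=q)

    if feature_labels is None:
        feature_labels = [f"f{j:05d}" for j in range(len(mean))]
    return CoefficientInference(
        feature_labels=list(feature_labels),
        boot_mean=mean,
        boot_sd=sd,
        z=z,
        p=p,
        significant=significant,
        zero_sd=zero_sd,
        B=B,
        q=q,
    )
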