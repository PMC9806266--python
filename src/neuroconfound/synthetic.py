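"""Synthetic multimodal cohorts with a planted sex confound and strength signal.

The generator emulates the structure of a young-adult neuroimaging cohort in
which a binary attribute (sex) both shifts the continuous outcome (a grip
strength score, bimodal across sexes) and loads onto every feature block.
A second, sex-independent latent ("neural strength factor") carries the part
of the outcome that survives confound correction.  Tabular blocks are
low-rank signal plus noise; the timeseries block perturbs a base covariance
so that tangent connectivity downstream inherits both signals.

Model
-----
For subject ``i`` with sex code ``s_i`` (-1 female, +1 male) and latent
``z_i ~ N(0, 1)``::

    strength_i = mu(sex_i) + sd(sex_i) * (rho_z * z_i + sqrt(1 - rho_z^2) * eps_i)
    X_block[i] = w_sex * s_i * u^T + w_strength * z_i * v^T + noise
    Sigma_i    = Sigma_base + a_sex * s_i * M_sex + a_strength * z_i * M_str

``u`` and ``v`` are fixed unit loading vectors per block (optionally sparse,
so ground-truth null features exist for inference tests); ``Sigma_i`` is
projected to positive definite before timeseries are drawn.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "TimeseriesSet",
    "FeatureBlock",
    "generate_cohort",
    "family_split",
    "morphometry_labels",
    "write_cohort",
]

#: default tabular block dimensionalities: 155 gray-matter morphometry
#: features (68 cortical thickness + 68 cortical area + 19 subcortical
#: volumes), 48 white-matter FA regions, and a task-activation block kept at
#: desk scale (the real task maps are voxelwise and far larger).
DEFAULT_BLOCK_DIMS = {"gm": 155, "wm": 48, "task": 2000}


def morphometry_labels() -> list[str]:
    """Labels for the 155-feature gray-matter block: 68 + 68 + 19.

    34 bilateral cortical regions contribute a thickness and an area measure
    per hemisphere; 9 bilateral subcortical regions plus the brainstem
    contribute volumes.
    """
    labels = [f"thickness_{h}_{i:02d}" for h in ("lh", "rh") for i in range(1, 35)]
    labels += [f"area_{h}_{i:02d}" for h in ("lh", "rh") for i in range(1, 35)]
    labels += [f"volume_{h}_{i:02d}" for h in ("lh", "rh") for i in range(1, 10)]
    labels += ["volume_brainstem"]
    return labels


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Strength means/SDs default to the study's training-cohort values
    (female 109.1 +/- 6.0, male 125.5 +/- 9.1 score units, Cohen's d ~ 2.1).
    ``rho_z`` is the correlation between the latent neural factor and the
    within-sex strength residual; 0.3 leaves a small sex-independent signal.
    """

    n_subjects: int = 1045
    p_female: float = 0.54
    mu_strength_f: float = 109.1
    mu_strength_m: float = 125.5
    sd_strength_f: float = 6.0
    sd_strength_m: float = 9.1
    rho_z: float = 0.3
    block_dims: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BLOCK_DIMS))
    w_sex: dict[str, float] | float = 2.0
    w_strength: dict[str, float] | float = 1.0
    noise_sd: dict[str, float] | float = 1.0
    n_informative: dict[str, int] | None = None
    equal_loadings: bool = False
    ts_regions: int = 122
    ts_timepoints: int = 160
    n_runs: int = 2
    ts_dt: float = 0.72
    a_sex: float = 0.2
    a_strength: float = 0.1
    with_timeseries: bool = True
    n_families: int = 450
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_female < 1.0:
            raise ValueError("p_female must lie strictly between 0 and 1")
        for sd in (self.sd_strength_f, self.sd_strength_m):
            if sd <= 0:
                raise ValueError("strength SDs must be positive")
        if not -1.0 <= self.rho_z <= 1.0:
            raise ValueError("rho_z must lie in [-1, 1]")
        for name, p in self.block_dims.items():
            if p <= 0:
                raise ValueError(f"block {name!r} must have a positive feature count")
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")

    def _per_block(self, value, name: str) -> float:
        if isinstance(value, dict):
            return float(value.get(name, 1.0))
        return float(value)

    def sex_loading(self, name: str) -> float:
        return self._per_block(self.w_sex, name)

    def strength_loading(self, name: str) -> float:
        return self._per_block(self.w_strength, name)

    def block_noise_sd(self, name: str) -> float:
        return self._per_block(self.noise_sd, name)


@dataclass
class FeatureBlock:
    """One modality's subjects x features matrix, row-aligned to the cohort."""

    block_name: str
    matrix: np.ndarray
    feature_labels: list[str]

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[1] != len(self.feature_labels):
            raise ValueError("feature_labels length must match matrix columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self, subject_ids) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_labels)
        df.insert(0, "subject_id", list(subject_ids))
        return df


@dataclass
class TimeseriesSet:
    """Per-subject, per-run region x timepoint matrices plus sampling interval."""

    runs: dict[str, list[np.ndarray]]
    dt: float

    @property
    def n_regions(self) -> int:
        first = next(iter(self.runs.values()))
        return first[0].shape[0]

    def for_subjects(self, subject_ids) -> list[list[np.ndarray]]:
        return [self.runs[s] for s in subject_ids]


@dataclass
class BlockTruth:
    """Ground-truth loadings for one block (for recovery tests)."""

    sex_loading: np.ndarray
    strength_loading: np.ndarray
    informative_mask: np.ndarray


@dataclass
class Cohort:
    """A generated cohort: metadata, feature blocks, timeseries and truth."""

    subjects: pd.DataFrame
    blocks: dict[str, FeatureBlock]
    timeseries: TimeseriesSet | None
    truth: dict[str, BlockTruth]
    sex_code: np.ndarray
    z_strength: np.ndarray
    config: GeneratorConfig

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _unit_loading(
    rng: np.random.Generator, p: int, k: int | None, equal: bool = False
) -> np.ndarray:
    """Random unit vector, optionally supported on k coordinates.

    With ``equal=True`` the support entries are +/- 1/sqrt(k): every planted
    feature carries the same effect magnitude (used by recovery studies so
    "planted" means "detectable at the configured signal level").
    """
    v = np.zeros(p)
    if k is None or k >= p:
        k = p
        support = np.arange(p)
    else:
        support = rng.choice(p, size=k, replace=False)
    if equal:
        v[support] = rng.choice([-1.0, 1.0], size=k)
    else:
        v[support] = rng.standard_normal(k)
    return v / np.linalg.norm(v)


def _spd_floor(mat: np.ndarray, rel_floor: float = 1e-3) -> np.ndarray:
    """Project a symmetric matrix to SPD by flooring eigenvalues.

    The floor is relative to the mean eigenvalue, which keeps downstream
    shrinkage estimators well conditioned.
    """
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    floor = rel_floor * float(np.mean(np.abs(vals)))
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _subject_covariance(
    base: np.ndarray,
    m_sex: np.ndarray,
    m_str: np.ndarray,
    s: float,
    z: float,
    a_sex: float,
    a_str: float,
    max_halvings: int = 10,
) -> np.ndarray:
    """Perturbed covariance, shrinking the perturbation if needed for SPD."""
    scale = 1.0
    for _ in range(max_halvings + 1):
        sigma = base + scale * (a_sex * s * m_sex + a_str * z * m_str)
        vals = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
        if vals.min() > 0:
            return _spd_floor(sigma)
        scale *= 0.5
    raise RuntimeError(
        "subject covariance not positive definite even after shrinking the "
        f"perturbation by 2**{max_halvings}"
    )


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a full synthetic cohort from ``config``.

    Fixing ``config.seed`` reproduces the cohort bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    female = rng.random(n) < config.p_female
    s = np.where(female, -1.0, 1.0)
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    mu = np.where(female, config.mu_strength_f, config.mu_strength_m)
    sd = np.where(female, config.sd_strength_f, config.sd_strength_m)
    rho = config.rho_z
    strength = mu + sd * (rho * z + np.sqrt(1.0 - rho**2) * eps)

    age = rng.uniform(22.0, 37.0, size=n)
    right_handed = rng.random(n) < 0.91
    family = rng.integers(0, config.n_families, size=n)

    subjects = pd.DataFrame(
        {
            "subject_id": [f"sub{i:05d}" for i in range(n)],
            "sex": np.where(female, "F", "M"),
            "strength": strength,
            "age": age,
            "family_id": [f"fam{f:04d}" for f in family],
            "handedness": np.where(right_handed, "right", "other"),
        }
    )

    blocks: dict[str, FeatureBlock] = {}
    truth: dict[str, BlockTruth] = {}
    for name, p in config.block_dims.items():
        k = None if config.n_informative is None else config.n_informative.get(name)
        u = _unit_loading(rng, p, k, equal=config.equal_loadings)
        v = _unit_loading(rng, p, k, equal=config.equal_loadings)
        w_s = config.sex_loading(name)
        w_z = config.strength_loading(name)
        noise = config.block_noise_sd(name) * rng.standard_normal((n, p))
        X = w_s * np.outer(s, u) + w_z * np.outer(z, v) + noise
        if name == "gm" and p == 155:
            labels = morphometry_labels()
        else:
            labels = [f"{name}_f{j:04d}" for j in range(p)]
        blocks[name] = FeatureBlock(name, X, labels)
        truth[name] = BlockTruth(
            sex_loading=w_s * u,
            strength_loading=w_z * v,
            informative_mask=(u != 0) | (v != 0),
        )

    timeseries = None
    if config.with_timeseries:
        r = config.ts_regions
        # AR(1)-like base covariance: well conditioned, realistic off-diagonals
        idx = np.arange(r)
        base = 0.3 ** np.abs(idx[:, None] - idx[None, :])
        m_sex = rng.standard_normal((r, r))
        m_sex = 0.5 * (m_sex + m_sex.T)
        m_sex /= np.linalg.norm(m_sex)
        m_str = rng.standard_normal((r, r))
        m_str = 0.5 * (m_str + m_str.T)
        m_str /= np.linalg.norm(m_str)
        runs: dict[str, list[np.ndarray]] = {}
        for i, sid in enumerate(subjects["subject_id"]):
            sigma = _subject_covariance(
                base, m_sex, m_str, s[i], z[i], config.a_sex, config.a_strength
            )
            chol = np.linalg.cholesky(sigma)
            runs[sid] = [
                chol @ rng.standard_normal((r, config.ts_timepoints))
                for _ in range(config.n_runs)
            ]
        timeseries = TimeseriesSet(runs=runs, dt=config.ts_dt)

    return Cohort(
        subjects=subjects,
        blocks=blocks,
        timeseries=timeseries,
        truth=truth,
        sex_code=s,
        z_strength=z,
        config=config,
    )


def family_split(
    subjects: pd.DataFrame, n_test: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Hold out ``n_test`` unrelated subjects, at most one per family.

    Mirrors the unrelated-test-subject design: test subjects come from
    distinct families so that familial (genetic/environmental) structure
    never spans the train/test boundary.  Returns boolean (train, test)
    masks that are disjoint and exhaustive.
    """
    families = subjects["family_id"].to_numpy()
    unique_families = np.unique(families)
    if n_test > len(unique_families):
        raise ValueError(
            f"requested {n_test} test subjects from distinct families but only "
            f"{len(unique_families)} families exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(unique_families, size=n_test, replace=False)
    test_mask = np.zeros(len(subjects), dtype=bool)
    for fam in chosen:
        members = np.flatnonzero(families == fam)
        test_mask[rng.choice(members)] = True
    return ~test_mask, test_mask


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the cohort as delimited text plus a JSON manifest.

    Subject table and each block go to one TSV each; timeseries go to one
    TSV per subject per run (regions x timepoints).  Returns the manifest
    path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    subj_path = out / "subjects.tsv"
    cohort.subjects.to_csv(subj_path, sep="\t", index=False)
    paths["subjects"] = subj_path.name

    block_paths = {}
    for name, block in cohort.blocks.items():
        p = out / f"block_{name}.tsv"
        block.to_frame(cohort.subjects["subject_id"]).to_csv(p, sep="\t", index=False)
        block_paths[name] = p.name
    paths["blocks"] = block_paths

    if cohort.timeseries is not None:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        ts_paths: dict[str, list[str]] = {}
        for sid, mats in cohort.timeseries.runs.items():
            ts_paths[sid] = []
            for r, mat in enumerate(mats):
                p = ts_dir / f"{sid}_run{r}.tsv"
                np.savetxt(p, mat, delimiter="\t")
                ts_paths[sid].append(str(p.relative_to(out)))
        paths["timeseries"] = ts_paths
        paths["ts_dt"] = cohort.timeseries.dt

    cfg = dataclasses.asdict(cohort.config)
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"config": cfg, "paths": paths}, indent=2))
    return manifest
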