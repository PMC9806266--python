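import numpy as np
import pytest

from neuroconfound import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tabular-only cohort: 120 subjects, two small blocks."""
    cfg = GeneratorConfig(
        n_subjects=120,
        block_dims={"gm": 30, "wm": 10},
        with_timeseries=False,
        n_families=60,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def ts_cohort():
    """Tiny cohort with timeseries for connectivity tests."""
    cfg = GeneratorConfig(
        n_subjects=8,
        block_dims={"gm": 5},
        ts_regions=10,
        ts_timepoints=80,
        n_runs=2,
        n_families=8,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_spd(rng, r, cond=10.0):
    """Random SPD matrix with bounded condition number."""
    q, _ = np.linalg.qr(rng.standard_normal((r, r)))
    vals = np.exp(rng.uniform(0, np.log(cond), size=r))
    return (q * vals) @ q.T
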