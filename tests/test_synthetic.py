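"""Cohort generator: determinism, planted effect sizes, family splitting."""

import numpy as np
import pandas as pd
import pytest

from neuroconfound import (
    GeneratorConfig,
    GroupSummary,
    cohens_d,
    family_split,
    generate_cohort,
)
from neuroconfound.synthetic import morphometry_labels, write_cohort


def test_seed_reproduces_cohort_bit_identically():
    cfg = GeneratorConfig(
        n_subjects=50, block_dims={"gm": 20}, ts_regions=6, ts_timepoints=40,
        n_families=25, seed=3,
    )
    a, b = generate_cohort(cfg), generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.subjects, b.subjects)
    assert np.array_equal(a.blocks["gm"].matrix, b.blocks["gm"].matrix)
    sid = a.subjects["subject_id"].iloc[0]
    assert np.array_equal(a.timeseries.runs[sid][0], b.timeseries.runs[sid][0])


def test_default_strength_distribution_matches_study_effect_size():
    """At n=970 the sex gap in strength lands near Cohen's d = 2.1."""
    cfg = GeneratorConfig(
        n_subjects=970, block_dims={"gm": 5}, with_timeseries=False, seed=42
    )
    cohort = generate_cohort(cfg)
    s = cohort.subjects
    d = cohens_d(
        GroupSummary.from_values(s.loc[s.sex == "F", "strength"]),
        GroupSummary.from_values(s.loc[s.sex == "M", "strength"]),
    )
    assert abs(d - 2.1) < 0.15


@pytest.mark.parametrize("n,tol_factor", [(500, 1.0), (4000, 1.0)])
def test_group_means_converge_at_root_n_rate(n, tol_factor):
    cfg = GeneratorConfig(
        n_subjects=n, block_dims={"gm": 2}, with_timeseries=False, seed=n
    )
    s = generate_cohort(cfg).subjects
    for sex, mu, sd in (("F", 109.1, 6.0), ("M", 125.5, 9.1)):
        vals = s.loc[s.sex == sex, "strength"]
        # 4-sigma band on the mean of ~n/2 draws
        assert abs(vals.mean() - mu) < tol_factor * 4 * sd / np.sqrt(len(vals))
        assert abs(vals.std(ddof=1) - sd) < 6 * sd / np.sqrt(len(vals))


def test_no_sex_signal_leaves_classification_at_chance():
    """w_sex=0 with equal sex means: held-out sex accuracy hovers at 0.5."""
    from neuroconfound import PredictionPipeline

    cfg = GeneratorConfig(
        n_subjects=300,
        block_dims={"gm": 20},
        w_sex=0.0,
        w_strength=0.0,
        mu_strength_f=100.0,
        mu_strength_m=100.0,
        sd_strength_f=5.0,
        sd_strength_m=5.0,
        with_timeseries=False,
        seed=5,
    )
    cohort = generate_cohort(cfg)
    X = cohort.blocks["gm"].matrix
    sex = cohort.subjects["sex"].to_numpy()
    pipe = PredictionPipeline(task="classification", fixed_C=1.0)
    pipe.fit(X[:200], sex[:200])
    acc = pipe.evaluate(X[200:], sex[200:]).metrics["accuracy"]
    assert 0.3 < acc < 0.7


def test_pure_noise_target_gives_nonpositive_r2():
    """rho_z=0 and w_strength=0: features carry no strength information."""
    from neuroconfound import PredictionPipeline

    cfg = GeneratorConfig(
        n_subjects=300,
        block_dims={"gm": 20},
        w_sex=0.0,
        w_strength=0.0,
        rho_z=0.0,
        mu_strength_f=100.0,
        mu_strength_m=100.0,
        sd_strength_f=5.0,
        sd_strength_m=5.0,
        with_timeseries=False,
        seed=9,
    )
    cohort = generate_cohort(cfg)
    X = cohort.blocks["gm"].matrix
    y = cohort.subjects["strength"].to_numpy()
    r2s = []
    for split_seed in range(5):
        rng = np.random.default_rng(split_seed)
        order = rng.permutation(300)
        tr, te = order[:220], order[220:]
        pipe = PredictionPipeline(task="regression", fixed_C=1.0)
        pipe.fit(X[tr], y[tr])
        r2s.append(pipe.evaluate(X[te], y[te]).metrics["r2"])
    assert np.mean(r2s) <= 0.02


def test_morphometry_block_labels_155():
    labels = morphometry_labels()
    assert len(labels) == 155
    assert sum(1 for l in labels if l.startswith("thickness")) == 68
    assert sum(1 for l in labels if l.startswith("area")) == 68
    assert sum(1 for l in labels if l.startswith("volume")) == 19


def test_informative_support_is_respected():
    cfg = GeneratorConfig(
        n_subjects=50,
        block_dims={"gm": 40},
        n_informative={"gm": 6},
        with_timeseries=False,
        seed=1,
    )
    cohort = generate_cohort(cfg)
    truth = cohort.truth["gm"]
    assert truth.informative_mask.sum() <= 12  # two supports of 6
    assert np.all(truth.sex_loading[~truth.informative_mask] == 0)
    assert np.all(truth.strength_loading[~truth.informative_mask] == 0)


class TestFamilySplit:
    def test_ten_families_of_two(self):
        subjects = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(20)],
                "family_id": [f"f{i // 2}" for i in range(20)],
            }
        )
        train, test = family_split(subjects, n_test=10, seed=0)
        assert test.sum() == 10 and train.sum() == 10
        fams = subjects.loc[test, "family_id"]
        assert fams.nunique() == 10

    def test_single_family_errors(self):
        subjects = pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "family_id": ["f0", "f0", "f0"]}
        )
        with pytest.raises(ValueError, match="families"):
            family_split(subjects, n_test=2, seed=0)

    def test_no_test_pair_shares_family_exhaustive(self):
        """Brute-force pair scan on a 75-singleton + related cohort."""
        fam = [f"u{i}" for i in range(75)] + [f"r{i % 40}" for i in range(895)]
        rng = np.random.default_rng(8)
        fam = list(rng.permutation(fam))
        subjects = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(970)], "family_id": fam}
        )
        train, test = family_split(subjects, n_test=75, seed=2)
        assert test.sum() == 75
        assert not np.any(train & test)
        assert np.all(train | test)
        test_fams = subjects.loc[test, "family_id"].to_numpy()
        for i in range(len(test_fams)):
            for j in range(i + 1, len(test_fams)):
                assert test_fams[i] != test_fams[j]


def test_write_cohort_roundtrip(tmp_path, ts_cohort):
    manifest = write_cohort(ts_cohort, tmp_path)
    assert manifest.exists()
    subj = pd.read_csv(tmp_path / "subjects.tsv", sep="\t")
    assert len(subj) == ts_cohort.n_subjects
    block = pd.read_csv(tmp_path / "block_gm.tsv", sep="\t")
    np.testing.assert_allclose(
        block.iloc[:, 1:].to_numpy(), ts_cohort.blocks["gm"].matrix, rtol=1e-6
    )
    sid = ts_cohort.subjects["subject_id"].iloc[0]
    ts = np.loadtxt(tmp_path / "timeseries" / f"{sid}_run0.tsv", delimiter="\t")
    np.testing.assert_allclose(ts, ts_cohort.timeseries.runs[sid][0], rtol=1e-6)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(p_female=1.0)
    with pytest.raises(ValueError):
        GeneratorConfig(sd_strength_f=0.0)
    with pytest.raises(ValueError):
        GeneratorConfig(block_dims={"gm": 0})
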