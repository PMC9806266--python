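"""Tangent connectivity: filtering, shrinkage, geometric mean, embedding."""

import numpy as np
import pytest

from neuroconfound import (
    TangentConnectivity,
    TangentReference,
    bandpass,
    connectivity_features,
    geometric_mean,
    shrinkage_covariance,
    tangent_embed,
)
from conftest import random_spd

DT = 0.72


class TestBandpass:
    def test_constant_signal_suppressed(self):
        ts = np.ones((3, 200))
        out = bandpass(ts, 0.008, 0.100, DT)
        assert np.max(np.abs(out)) < 1e-2

    @pytest.mark.parametrize(
        "freq,kind", [(0.05, "pass"), (0.2, "stop")]
    )
    def test_sinusoid_amplitude(self, freq, kind):
        t = np.arange(600) * DT
        ts = np.sin(2 * np.pi * freq * t)[None, :]
        out = bandpass(ts, 0.008, 0.100, DT)
        # compare FFT amplitude at the driving frequency
        f = np.fft.rfftfreq(len(t), DT)
        k = np.argmin(np.abs(f - freq))
        a_in = np.abs(np.fft.rfft(ts[0]))[k]
        a_out = np.abs(np.fft.rfft(out[0]))[k]
        if kind == "pass":
            assert a_out > 0.95 * a_in
        else:
            assert a_out < 0.10 * a_in

    def test_shape_preserved(self, rng):
        ts = rng.standard_normal((5, 111))
        assert bandpass(ts, 0.008, 0.100, DT).shape == (5, 111)

    def test_high_above_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros((2, 50)), 0.008, 0.8, DT)


class TestShrinkageCovariance:
    def test_iid_normal_converges_to_identity(self, rng):
        ts = rng.standard_normal((4, 20000))
        cov = shrinkage_covariance(ts)
        assert np.max(np.abs(cov - np.eye(4))) < 0.05

    def test_single_timepoint_errors(self):
        with pytest.raises(ValueError):
            shrinkage_covariance(np.ones((3, 1)))

    def test_matches_ledoit_wolf_formula(self):
        """Brute-force Ledoit-Wolf shrinkage on a hand-sized sample."""
        X = np.array([[1.0, 2.0, 0.5, -1.0], [0.3, -0.7, 1.2, 0.9]])  # 2 regions, T=4
        obs = X.T - X.T.mean(axis=0)
        T, p = obs.shape
        S = obs.T @ obs / T
        mu = np.trace(S) / p
        d2 = np.sum((S - mu * np.eye(p)) ** 2) / p
        b_bar2 = (
            sum(np.sum((np.outer(x, x) - S) ** 2) for x in obs) / T**2 / p
        )
        b2 = min(b_bar2, d2)
        shrink = b2 / d2
        expected = shrink * mu * np.eye(p) + (1 - shrink) * S
        np.testing.assert_allclose(shrinkage_covariance(X), expected, atol=1e-12)

    def test_positive_definite_when_t_less_than_r(self, rng):
        ts = rng.standard_normal((20, 8))  # 20 regions, 8 timepoints
        vals = np.linalg.eigvalsh(shrinkage_covariance(ts))
        assert vals.min() > 0


class TestGeometricMean:
    def test_single_matrix_is_itself(self, rng):
        c = random_spd(rng, 5)
        ref = geometric_mean([c])
        np.testing.assert_allclose(ref.covariance, c, atol=1e-8)

    def test_identity_pair(self):
        ref = geometric_mean([np.eye(4), np.eye(4)])
        np.testing.assert_allclose(ref.covariance, np.eye(4), atol=1e-10)

    def test_commuting_diagonals_closed_form(self, rng):
        """For commuting SPD matrices the mean is elementwise sqrt(a*b)."""
        a = np.diag(rng.uniform(0.5, 3.0, size=6))
        b = np.diag(rng.uniform(0.5, 3.0, size=6))
        ref = geometric_mean([a, b], tol=1e-10)
        expected = np.diag(np.sqrt(np.diag(a) * np.diag(b)))
        np.testing.assert_allclose(ref.covariance, expected, atol=1e-8)

    def test_nonconvergence_carries_log(self, rng):
        covs = [random_spd(rng, 4, cond=100) for _ in range(5)]
        with pytest.raises(RuntimeError, match="step norms"):
            geometric_mean(covs, tol=1e-16, max_iter=1)

    def test_matches_nilearn_reference(self, rng):
        from nilearn.connectome.connectivity_matrices import _geometric_mean

        covs = [random_spd(rng, 6) for _ in range(4)]
        ours = geometric_mean(covs, tol=1e-10).covariance
        theirs = _geometric_mean([c.copy() for c in covs], max_iter=100, tol=1e-12)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestTangentEmbed:
    def test_122_regions_give_7381_features(self, rng):
        r = 122
        ref = TangentReference(covariance=np.eye(r), whitener=np.eye(r))
        vec = tangent_embed(random_spd(rng, r), ref)
        assert vec.shape == (7381,)

    def test_cov_equal_ref_gives_zero_vector(self, rng):
        c = random_spd(rng, 7)
        ref = geometric_mean([c])
        assert np.max(np.abs(tangent_embed(c, ref))) < 1e-8

    def test_identity_ref_diagonal_cov_gives_zero_vector(self):
        ref = TangentReference(covariance=np.eye(5), whitener=np.eye(5))
        vec = tangent_embed(np.diag([1.0, 2.0, 0.5, 3.0, 1.5]), ref)
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)

    def test_non_spd_input_errors(self, rng):
        ref = TangentReference(covariance=np.eye(3), whitener=np.eye(3))
        bad = np.diag([1.0, -1.0, 2.0])
        with pytest.raises(ValueError, match="positive definite"):
            tangent_embed(bad, ref)

    def test_affine_invariance(self, rng):
        """Tangent vectors are unchanged under joint congruence transform."""
        from neuroconfound.connectivity import _spd_log

        c1, c2 = random_spd(rng, 5), random_spd(rng, 5)
        ref = geometric_mean([c1, c2], tol=1e-12)

        A = rng.standard_normal((5, 5))
        A += 5 * np.eye(5)  # well conditioned
        c1t, c2t = A @ c1 @ A.T, A @ c2 @ A.T
        reft = geometric_mean([c1t, c2t], tol=1e-12)
        # the whitened-log spectrum (hence the Frobenius tangent norm) is
        # invariant under the joint congruence transform
        for c, ct in ((c1, c1t), (c2, c2t)):
            m = _spd_log(ref.whitener @ c @ ref.whitener)
            mt = _spd_log(reft.whitener @ ct @ reft.whitener)
            np.testing.assert_allclose(
                np.sort(np.linalg.eigvalsh(m)),
                np.sort(np.linalg.eigvalsh(mt)),
                atol=1e-6,
            )

    def test_matches_nilearn_tangent_pipeline(self, rng):
        """End-to-end cross-check against nilearn's tangent connectivity."""
        from nilearn.connectome import ConnectivityMeasure
        from sklearn.covariance import LedoitWolf

        series = [rng.standard_normal((60, 6)) for _ in range(5)]  # T x r
        cm = ConnectivityMeasure(
            cov_estimator=LedoitWolf(), kind="tangent", vectorize=False,
            standardize=False,
        )
        theirs = cm.fit_transform(series)

        covs = [shrinkage_covariance(s.T) for s in series]
        ref = geometric_mean(covs, tol=1e-10, max_iter=200)
        rows, cols = np.tril_indices(6, k=-1)
        for mat, cov in zip(theirs, covs):
            ours = tangent_embed(cov, ref)
            np.testing.assert_allclose(ours, mat[rows, cols], atol=1e-4)


class TestRunAveraging:
    def test_identical_runs_equal_single_run(self, rng):
        run = rng.standard_normal((4, 100))
        ref = geometric_mean([shrinkage_covariance(run)])
        one = connectivity_features([run], ref)
        two = connectivity_features([run, run.copy()], ref)
        np.testing.assert_allclose(one, two, atol=1e-12)

    def test_two_runs_average(self, rng):
        r1, r2 = rng.standard_normal((4, 100)), rng.standard_normal((4, 100))
        ref = geometric_mean(
            [shrinkage_covariance(r1), shrinkage_covariance(r2)], tol=1e-10
        )
        avg = connectivity_features([r1, r2], ref)
        expected = 0.5 * (
            connectivity_features([r1], ref) + connectivity_features([r2], ref)
        )
        np.testing.assert_allclose(avg, expected, atol=1e-12)

    def test_zero_runs_error(self, rng):
        ref = TangentReference(covariance=np.eye(3), whitener=np.eye(3))
        with pytest.raises(ValueError):
            connectivity_features([], ref)


class TestTrainOnlyReference:
    def test_transform_never_updates_reference(self, ts_cohort):
        from neuroconfound.preprocessing import state_hash

        ids = ts_cohort.subjects["subject_id"].tolist()
        ext = TangentConnectivity(dt=ts_cohort.timeseries.dt)
        ext.fit(ts_cohort.timeseries.for_subjects(ids[:5]))
        h1 = state_hash(ext.state_arrays())
        feats = ext.transform(ts_cohort.timeseries.for_subjects(ids[5:]))
        assert feats.shape == (3, 10 * 9 // 2)
        assert state_hash(ext.state_arrays()) == h1

    def test_arithmetic_mean_option(self, ts_cohort):
        ids = ts_cohort.subjects["subject_id"].tolist()
        ext = TangentConnectivity(dt=ts_cohort.timeseries.dt, mean_type="arithmetic")
        ext.fit(ts_cohort.timeseries.for_subjects(ids[:4]))
        assert ext.reference_ is not None
        assert ext.reference_.iteration_log == []
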