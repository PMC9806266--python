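"""Pre-validated stacking: OOF construction and second-level behaviour."""

import numpy as np
import pytest

from neuroconfound import (
    MultimodalPipeline,
    PredictionPipeline,
    fit_stack,
    prevalidated_features,
)
from neuroconfound.stacking import OofMatrix


def fast_factory(**kw):
    def make():
        return PredictionPipeline(task="regression", fixed_C=1e3, **kw)

    return make


class TestPrevalidatedFeatures:
    def test_perfect_predictor_column_tracks_target(self, rng):
        n = 80
        y = rng.standard_normal(n)
        X = y[:, None] + 0.01 * rng.standard_normal((n, 1))
        oof = prevalidated_features(
            {"one": fast_factory()}, {"one": X}, y, folds=10, seed=0
        )
        r = np.corrcoef(oof.matrix[:, 0], y)[0, 1]
        assert r > 0.99

    def test_noise_pipeline_column_uncorrelated(self, rng):
        n = 200
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        oof = prevalidated_features(
            {"noise": fast_factory()}, {"noise": X}, y, folds=10, seed=0
        )
        assert abs(np.corrcoef(oof.matrix[:, 0], y)[0, 1]) < 0.15

    def test_leave_one_out_excludes_own_row(self, rng):
        """With folds=n every OOF entry comes from a fit without that row."""
        n = 12
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        oof = prevalidated_features(
            {"a": fast_factory()}, {"a": X}, y, folds=n, seed=0
        )
        assert sorted(oof.fold_assignment) == list(range(n))
        # flipping one row's target must not move that row's own prediction
        y2 = y.copy()
        y2[3] += 100.0
        oof2 = prevalidated_features(
            {"a": fast_factory()}, {"a": X}, y2, folds=n, seed=0
        )
        assert oof2.matrix[3, 0] == pytest.approx(oof.matrix[3, 0])

    def test_fold_assignment_shared_across_pipelines(self, rng):
        n = 40
        y = rng.standard_normal(n)
        blocks = {"a": rng.standard_normal((n, 3)), "b": rng.standard_normal((n, 3))}
        oof = prevalidated_features(
            {"a": fast_factory(), "b": fast_factory()}, blocks, y, folds=5, seed=1
        )
        assert oof.matrix.shape == (n, 2)
        assert oof.pipeline_names == ["a", "b"]


class TestFitStack:
    def test_column_equal_to_target_gets_unit_weight(self, rng):
        y = rng.standard_normal(50)
        other = rng.standard_normal(50)
        oof = OofMatrix(
            matrix=np.column_stack([y, other]),
            fold_assignment=np.zeros(50, dtype=int),
            pipeline_names=["exact", "noise"],
        )
        stack = fit_stack(oof, y, task="regression")
        np.testing.assert_allclose(stack.coef_, [1.0, 0.0], atol=1e-8)
        assert stack.intercept_ == pytest.approx(0.0, abs=1e-8)

    def test_duplicate_columns_split_weight_but_match_fit(self, rng):
        y = rng.standard_normal(50)
        col = y + 0.1 * rng.standard_normal(50)
        single = OofMatrix(col[:, None], np.zeros(50, int), ["a"])
        double = OofMatrix(
            np.column_stack([col, col]), np.zeros(50, int), ["a", "b"]
        )
        f1 = fit_stack(single, y)
        f2 = fit_stack(double, y)
        np.testing.assert_allclose(
            f1.predict(single.matrix), f2.predict(double.matrix), atol=1e-6
        )

    def test_all_noise_training_r2_matches_k_over_n(self):
        """OLS on k random regressors explains ~k/n of variance by chance."""
        n, k, reps = 50, 3, 300
        r2s = []
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(n)
            M = rng.standard_normal((n, k))
            oof = OofMatrix(M, np.zeros(n, int), list("abc"))
            stack = fit_stack(oof, y)
            resid = y - stack.predict(M)
            r2s.append(1 - resid.var() / y.var())
        assert np.mean(r2s) == pytest.approx(k / n, abs=0.02)


class TestMultimodalPipeline:
    def _independent_blocks(self, seed, n=150):
        rng = np.random.default_rng(seed)
        u1, u2 = rng.standard_normal(n), rng.standard_normal(n)
        y = u1 + u2 + 0.5 * rng.standard_normal(n)
        blocks = {
            "a": u1[:, None] + 0.3 * rng.standard_normal((n, 4)),
            "b": u2[:, None] + 0.3 * rng.standard_normal((n, 4)),
        }
        return blocks, y

    def test_stack_beats_best_single_block(self):
        """Independent block signals: the stack rarely loses to either block."""
        wins = 0
        for seed in range(20):
            blocks, y = self._independent_blocks(seed, n=150)
            tr = slice(0, 100)
            te = slice(100, 150)
            blocks_tr = {k: v[tr] for k, v in blocks.items()}
            blocks_te = {k: v[te] for k, v in blocks.items()}

            singles = []
            for name in blocks:
                pipe = PredictionPipeline(task="regression", fixed_C=1e3)
                pipe.fit(blocks_tr[name], y[tr])
                singles.append(
                    pipe.evaluate(blocks_te[name], y[te]).metrics["r2"]
                )
            mm = MultimodalPipeline(
                {n_: fast_factory() for n_ in blocks}, folds=10, seed=seed
            )
            mm.fit(blocks_tr, y[tr])
            r2 = mm.evaluate(blocks_te, y[te]).metrics["r2"]
            wins += r2 >= max(singles) - 0.05
        assert wins >= 16

    def test_missing_block_at_prediction_errors(self, rng):
        blocks, y = self._independent_blocks(0, n=60)
        mm = MultimodalPipeline({n_: fast_factory() for n_ in blocks}, folds=5)
        mm.fit(blocks, y)
        with pytest.raises(ValueError, match="missing"):
            mm.predict({"a": blocks["a"]})

    def test_label_shuffle_breaks_oof_signal(self, rng):
        """Pre-validation: permuted targets leave no exploitable OOF signal."""
        n = 100
        y = rng.standard_normal(n)
        X = y[:, None] + 0.1 * rng.standard_normal((n, 3))
        r2s = []
        for seed in range(10):
            yp = np.random.default_rng(seed).permutation(y)
            oof = prevalidated_features(
                {"a": fast_factory()}, {"a": X}, yp, folds=10, seed=0
            )
            stack = fit_stack(oof, yp)
            resid = yp - stack.predict(oof.matrix)
            r2s.append(1 - resid.var() / yp.var())
        # chance-level training R2 for one regressor: distribution covers 0
        assert min(r2s) < 0.05
        assert np.mean(r2s) < 0.1

    def test_classification_stack_with_stratified_folds(self, rng):
        n = 100
        g = rng.standard_normal(n)
        y = np.where(g + 0.3 * rng.standard_normal(n) > 0, "M", "F")
        blocks = {"a": g[:, None] + 0.5 * rng.standard_normal((n, 3))}

        def factory(fixed_C=1.0):
            return PredictionPipeline(task="classification", fixed_C=fixed_C)

        mm = MultimodalPipeline({"a": factory}, task="classification", folds=5)
        mm.fit(blocks, y)
        res = mm.evaluate(blocks, y)
        assert res.metrics["auc"] > 0.8
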