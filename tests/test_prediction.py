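import numpy as np
import pytest

from cogreserve import (
    CVConfig,
    GenConfig,
    cross_validated_r2,
    fit_block_model,
    generate_dataset,
    stack,
)
from cogreserve.prediction import (
    default_penalty_grid,
    outer_fold_labels,
    _column_standardizer,
    _nnls_affine,
)


class TestCVConfig:
    def test_defaults_match_nested_cv_design(self):
        cv = CVConfig(seed=0)
        assert cv.n_outer_folds == 10
        assert cv.n_inner_folds == 5
        assert cv.n_repeats == 20
        assert len(cv.penalty_grid) == 100  # 5 mixing weights x 20 strengths

    def test_rejects_bad_settings(self):
        with pytest.raises(ValueError):
            CVConfig(n_outer_folds=1, seed=0)
        with pytest.raises(ValueError):
            CVConfig(penalty_grid=(), seed=0)
        with pytest.raises(ValueError):
            CVConfig(penalty_grid=((1.5, 0.1),), seed=0)


class TestFolds:
    @pytest.mark.parametrize("n,k", [(23, 5), (100, 10), (10, 10)])
    def test_partition_is_disjoint_and_exhaustive(self, n, k):
        labels = outer_fold_labels(n, k, seed=3, repeat=1)
        assert labels.shape == (n,)
        counts = np.bincount(labels, minlength=k)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1

    def test_deterministic_and_repeat_sensitive(self):
        a = outer_fold_labels(50, 5, seed=3, repeat=0)
        b = outer_fold_labels(50, 5, seed=3, repeat=0)
        c = outer_fold_labels(50, 5, seed=3, repeat=1)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            outer_fold_labels(4, 5, seed=0, repeat=0)


class TestStandardizer:
    def test_binary_columns_not_scaled(self, rng):
        X = np.column_stack([rng.integers(0, 2, 50), rng.normal(0, 4.0, 50)])
        mean, scale = _column_standardizer(X, standardize=True)
        assert scale[0] == 1.0
        assert scale[1] == pytest.approx(X[:, 1].std())


class TestFitBlockModel:
    def test_realizable_linear_signal_recovered(self, rng):
        """A target exactly linear in one feature is predicted almost
        perfectly once a near-zero penalty is in the grid."""
        X = rng.normal(size=(120, 3))
        y = 2.0 * X[:, 0] + 1.0
        cv = CVConfig(
            n_outer_folds=5, n_inner_folds=3, n_repeats=1, seed=1,
            penalty_grid=((0.01, 1e-6), (0.01, 0.1)),
        )
        bp = fit_block_model(X, y, cv, repeat=0)
        assert cross_validated_r2(y, bp.oof_pred) > 0.99

    def test_pure_noise_target_near_zero_r2(self, rng):
        """y independent of X (n=200, p=50): mean out-of-fold R^2 over 20
        seeds stays at or below sampling tolerance."""
        cv_template = dict(n_outer_folds=10, n_inner_folds=5, n_repeats=1)
        r2s = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            X = g.normal(size=(200, 50))
            y = g.normal(size=200)
            cv = CVConfig(seed=seed, **cv_template)
            bp = fit_block_model(X, y, cv, repeat=0)
            r2s.append(cross_validated_r2(y, bp.oof_pred))
        assert np.mean(r2s) <= 0.05

    def test_every_subject_predicted_once(self, small_dataset, small_cv):
        _, data, _ = small_dataset
        bp = fit_block_model(data.block("A"), data.target, small_cv, repeat=0)
        assert bp.oof_pred.shape == (data.n_subjects,)
        assert not np.isnan(bp.oof_pred).any()
        assert len(bp.chosen_penalties) == small_cv.n_outer_folds

    def test_deterministic_given_seed_and_repeat(self, small_dataset, small_cv):
        _, data, _ = small_dataset
        a = fit_block_model(data.block("A"), data.target, small_cv, repeat=1)
        b = fit_block_model(data.block("A"), data.target, small_cv, repeat=1)
        np.testing.assert_array_equal(a.oof_pred, b.oof_pred)
        assert a.chosen_penalties == b.chosen_penalties

    def test_singleton_grid_skips_inner_cv(self, rng):
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + 0.1 * rng.normal(size=40)
        cv = CVConfig(
            n_outer_folds=4, n_inner_folds=2, n_repeats=1, seed=2,
            penalty_grid=((0.5, 0.05),),
        )
        bp = fit_block_model(X, y, cv, repeat=0)
        assert set(bp.chosen_penalties) == {(0.5, 0.05)}

    def test_constant_target_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        cv = CVConfig(n_outer_folds=3, n_inner_folds=2, n_repeats=1, seed=0,
                      penalty_grid=((0.5, 0.1),))
        with pytest.raises(ValueError, match="constant"):
            fit_block_model(X, np.ones(30), cv, repeat=0)

    def test_test_fold_rows_do_not_influence_their_prediction(self, rng):
        """Leakage guard: perturbing one subject's feature row changes only
        that subject's own prediction, not the fits of its test fold
        (training never includes test-fold rows, including standardization)."""
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0]) + rng.normal(size=60)
        cv = CVConfig(n_outer_folds=5, n_inner_folds=3, n_repeats=1, seed=3,
                      penalty_grid=((0.5, 0.1),))
        base = fit_block_model(X, y, cv, repeat=0)
        victim = 7
        fold = base.fold_labels[victim]
        X2 = X.copy()
        X2[victim] += 100.0  # gross perturbation of a held-out row
        mod = fit_block_model(X2, y, cv, repeat=0)
        same_fold = base.fold_labels == fold
        other = ~same_fold
        # all other folds' models trained on the perturbed row may change;
        # but subjects sharing the victim's test fold keep their predictions
        keep = same_fold.copy()
        keep[victim] = False
        np.testing.assert_allclose(
            mod.oof_pred[keep], base.oof_pred[keep], rtol=0, atol=1e-10
        )
        assert not np.allclose(mod.oof_pred[victim], base.oof_pred[victim])
        assert other.any()


class TestStack:
    def _perfect_pred(self, y, cv, repeat=0):
        from cogreserve.prediction import BlockPrediction

        labels = outer_fold_labels(len(y), cv.n_outer_folds, cv.seed, repeat)
        return BlockPrediction("perfect", y.copy(), ((0.5, 0.1),), repeat, labels)

    def test_perfect_block_gives_r2_one(self, rng):
        y = rng.normal(size=50)
        cv = CVConfig(n_outer_folds=5, n_inner_folds=2, n_repeats=1, seed=4,
                      penalty_grid=((0.5, 0.1),))
        sr = stack([self._perfect_pred(y, cv)], y, cv, repeat=0)
        assert cross_validated_r2(y, sr.oof_pred) == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_blocks_do_not_double_count(self, small_dataset, small_cv):
        _, data, _ = small_dataset
        bp = fit_block_model(data.block("A"), data.target, small_cv, repeat=0)
        single = stack([bp], data.target, small_cv, repeat=0)
        double = stack([bp, bp], data.target, small_cv, repeat=0)
        r1 = cross_validated_r2(data.target, single.oof_pred)
        r2 = cross_validated_r2(data.target, double.oof_pred)
        assert r2 == pytest.approx(r1, abs=1e-6)

    def test_mismatched_fold_assignment_rejected(self, small_dataset, small_cv):
        _, data, _ = small_dataset
        a = fit_block_model(data.block("A"), data.target, small_cv, repeat=0)
        b = fit_block_model(data.block("B"), data.target, small_cv, repeat=1)
        with pytest.raises(ValueError, match="repeat"):
            stack([a, b], data.target, small_cv, repeat=0)
        # same repeat index but forged labels -> leakage guard
        from cogreserve.prediction import BlockPrediction

        forged = BlockPrediction(
            b.block_name, b.oof_pred, b.chosen_penalties, 0,
            np.roll(a.fold_labels, 1),
        )
        with pytest.raises(ValueError, match="fold assignment"):
            stack([a, forged], data.target, small_cv, repeat=0)

    def test_independent_signals_combine_toward_sum(self):
        """Two blocks carrying independent halves of the signal: the stack
        beats each single block and approaches the combined share."""
        cfg = GenConfig(
            n_subjects=1000,
            block_schema=(("A", 10), ("B", 10)),
            signal_share={"A": 0.25, "B": 0.25},
            shared_share=0.0,
            reliability=0.9,
            feature_noise_sd=0.2,
            confound_blocks=(),
            seed=17,
        )
        data, gt = generate_dataset(cfg)
        cv = CVConfig(n_outer_folds=5, n_inner_folds=3, n_repeats=1, seed=17,
                      penalty_grid=tuple((l1, a) for l1 in (0.01, 0.5)
                                         for a in (0.01, 0.1, 1.0)))
        preds = [fit_block_model(data.block(n), data.target, cv, 0) for n in ("A", "B")]
        single = [cross_validated_r2(data.target, p.oof_pred) for p in preds]
        both = stack(preds, data.target, cv, 0)
        r_both = cross_validated_r2(data.target, both.oof_pred)
        assert r_both > max(single)
        assert r_both == pytest.approx(gt.oracle_r2(("A", "B")), abs=0.08)

    def test_nnls_affine_nonnegative_weights(self, rng):
        P = rng.normal(size=(100, 3))
        y = -2.0 * P[:, 0] + rng.normal(size=100)  # anti-correlated predictor
        intercept, w = _nnls_affine(P, y)
        assert (w >= 0).all()
        assert w[0] == 0.0  # cannot use the negatively-related column


class TestCrossValidatedR2:
    def test_perfect_and_mean_predictions(self, rng):
        y = rng.normal(size=20)
        assert cross_validated_r2(y, y) == pytest.approx(1.0)
        assert cross_validated_r2(y, np.full(20, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.0, 2.0, 3.0, 5.0])
        assert cross_validated_r2(y, yhat) == pytest.approx(0.8)

    def test_worse_than_mean_is_negative(self, rng):
        y = rng.normal(size=30)
        assert cross_validated_r2(y, -3 * y) < 0

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            cross_validated_r2(np.ones(5), np.zeros(5))


def test_default_grid_spans_mixing_weights():
    grid = default_penalty_grid()
    l1s = sorted({l1 for l1, _ in grid})
    assert l1s == [0.01, 0.25, 0.5, 0.75, 1.0]
    strengths = sorted({a for _, a in grid})
    assert len(strengths) == 20
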