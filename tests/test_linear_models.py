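"""OLS, Lasso-path, elastic-net and single-best-predictor fitting."""

import numpy as np
import pytest

from mrgain.data_model import split_segments
from mrgain.linear_models import (
    FitConfig,
    LinearROIModel,
    elastic_net_candidates,
    fit_elastic_net_grid,
    fit_lasso_path,
    fit_ols,
    fit_single_best_predictor,
    lasso_candidates,
    predict,
    validation_error,
)

from .conftest import build_dataset


class TestOLS:
    def test_exact_linear_dependence(self, small_dataset, small_split, rng):
        # rebuild target as an exact combination so the training residual is 0
        A = small_dataset.activity.copy()
        A[:, 0] = 2.0 * A[:, 1] - 1.0 * A[:, 2]
        ds = build_dataset(A)
        m = fit_ols(ds, small_split, 0, [1, 2])
        np.testing.assert_allclose(m.weights, [2.0, -1.0], atol=1e-10)
        resid = ds.activity[small_split.train_slice, 0] - predict(m, ds, small_split.train)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_predictor_gets_zero_weight(self):
        T = 64
        t = np.arange(T)
        A = np.column_stack([np.cos(2 * np.pi * t / 8), np.sin(2 * np.pi * t / 8)])
        ds = build_dataset(A)
        m = fit_ols(ds, split_segments(T), 0, [1])
        assert abs(m.weights[0]) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        # brute-force oracle: centered normal equations on the raw scale
        for seed in range(3):
            r = np.random.default_rng(seed)
            A = r.standard_normal((100, 6))
            A[:, 0] += 0.5 * A[:, 3]
            ds = build_dataset(A)
            split = split_segments(100)
            m = fit_ols(ds, split, 0, [1, 2, 3, 4, 5])
            tr = split.train_slice
            X = ds.activity[tr][:, 1:6]
            y = ds.activity[tr, 0]
            Xc = X - X.mean(axis=0)
            yc = y - y.mean()
            w_oracle = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
            np.testing.assert_allclose(m.weights, w_oracle, atol=1e-8)

    def test_training_residuals_orthogonal_to_predictors(self, small_dataset, small_split):
        m = fit_ols(small_dataset, small_split, 0, [1, 2, 3, 4])
        tr = small_split.train_slice
        resid = small_dataset.activity[tr, 0] - predict(m, small_dataset, small_split.train)
        X = small_dataset.activity[tr][:, [1, 2, 3, 4]]
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(Xc.T @ resid, 0.0, atol=1e-8)

    def test_empty_predictors_rejected(self, small_dataset, small_split):
        with pytest.raises(ValueError, match="empty"):
            fit_ols(small_dataset, small_split, 0, [])

    def test_target_as_predictor_rejected(self, small_dataset, small_split):
        with pytest.raises(ValueError, match="own predictor"):
            fit_ols(small_dataset, small_split, 0, [0, 1])

    def test_underdetermined_warns_minimum_norm(self, rng):
        A = rng.standard_normal((16, 12))
        ds = build_dataset(A)
        with pytest.warns(UserWarning, match="minimum-norm"):
            m = fit_ols(ds, split_segments(16), 0, list(range(1, 12)))
        assert m.n_predictors == 11


class TestSingleBestPredictor:
    def test_perfect_copy(self, rng):
        A = rng.standard_normal((40, 4))
        A[:, 0] = A[:, 3]
        ds = build_dataset(A)
        m = fit_single_best_predictor(ds, split_segments(40), 0)
        assert list(m.predictors) == [3]
        np.testing.assert_allclose(m.weights, [1.0], atol=1e-10)

    def test_choice_uses_training_segment_only(self, rng):
        # predictor 1 is best on training rows, predictor 2 on validation rows
        T = 80
        split = split_segments(T)
        A = rng.standard_normal((T, 3)) * 0.1
        tr, va = split.train_slice, split.validation_slice
        y = rng.standard_normal(T)
        A[:, 0] = y
        A[tr, 1] = y[tr]
        A[va, 2] = y[va]
        ds = build_dataset(A)
        m = fit_single_best_predictor(ds, split, 0)
        assert list(m.predictors) == [1]

    def test_tie_breaks_to_lowest_roi_id(self, rng):
        T = 40
        y = np.sin(np.arange(T))
        A = np.column_stack([y, 2.0 * y, 2.0 * y])  # exact |corr| tie
        ds = build_dataset(A)
        m = fit_single_best_predictor(ds, split_segments(T), 0)
        assert list(m.predictors) == [1]


class TestLassoPath:
    def test_unregularized_limit_matches_ols(self, small_dataset, small_split):
        cfg = FitConfig(n_lasso_lambdas=60, lambda_min_ratio=1e-8)
        cands = lasso_candidates(small_dataset, small_split, 0, cfg)
        ols = fit_ols(small_dataset, small_split, 0, [1, 2, 3, 4])
        np.testing.assert_allclose(cands[-1].weights, ols.weights, atol=1e-4)

    def test_all_weights_zero_at_cmax(self, small_dataset, small_split):
        cands = lasso_candidates(small_dataset, small_split, 0, FitConfig(n_lasso_lambdas=20))
        assert np.all(cands[0].weights == 0.0)

    def test_selected_model_minimizes_validation_error(self, small_dataset, small_split):
        cfg = FitConfig(n_lasso_lambdas=50)
        cands = lasso_candidates(small_dataset, small_split, 0, cfg)
        best = fit_lasso_path(small_dataset, small_split, 0, cfg)
        assert best.validation_error <= min(c.validation_error for c in cands) + 1e-12

    def test_sparsity_nonincreasing_in_penalty(self, small_dataset, small_split):
        cands = lasso_candidates(small_dataset, small_split, 0, FitConfig(n_lasso_lambdas=80))
        nnz = [int(np.count_nonzero(c.weights)) for c in cands]  # c decreasing
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_zero_weight_predictors_dropped(self, small_dataset, small_split):
        best = fit_lasso_path(small_dataset, small_split, 0)
        assert np.all(best.weights != 0.0)


class TestElasticNet:
    def test_pure_l1_mix_reproduces_lasso(self, small_dataset, small_split):
        cfg = FitConfig(n_lasso_lambdas=40, n_enet_lambdas=40, enet_mixes=(1.0,))
        lasso = lasso_candidates(small_dataset, small_split, 0, cfg)
        enet = elastic_net_candidates(small_dataset, small_split, 0, cfg)
        assert len(lasso) == len(enet)
        for cl, ce in zip(lasso, enet):
            np.testing.assert_allclose(cl.weights, ce.weights, atol=1e-8)

    def test_unregularized_limit_matches_ols(self, small_dataset, small_split):
        cfg = FitConfig(n_enet_lambdas=40, enet_mixes=(0.5,), lambda_min_ratio=1e-8)
        cands = elastic_net_candidates(small_dataset, small_split, 0, cfg)
        ols = fit_ols(small_dataset, small_split, 0, [1, 2, 3, 4])
        np.testing.assert_allclose(cands[-1].weights, ols.weights, atol=1e-4)

    def test_grouping_effect_on_duplicated_predictors(self, rng):
        # two identical predictors: the L2 part spreads weight evenly,
        # whereas the pure Lasso concentrates it on one of the pair
        T = 80
        x = rng.standard_normal(T)
        z = rng.standard_normal(T)
        y = x + 0.5 * z + 0.05 * rng.standard_normal(T)
        A = np.column_stack([y, x, x.copy(), z])
        ds = build_dataset(A)
        split = split_segments(T)
        cfg = FitConfig(n_enet_lambdas=30, enet_mixes=(0.05,))
        cands = elastic_net_candidates(ds, split, 0, cfg, predictors=[1, 2, 3])
        mid = cands[len(cands) // 2]
        assert abs(mid.weights[0] - mid.weights[1]) < 1e-6
        lcands = lasso_candidates(ds, split, 0, FitConfig(n_lasso_lambdas=30), predictors=[1, 2, 3])
        lm = lcands[len(lcands) // 2]
        assert min(abs(lm.weights[0]), abs(lm.weights[1])) < 1e-10 < max(
            abs(lm.weights[0]), abs(lm.weights[1])
        )

    def test_grid_selection_beats_every_candidate(self, small_dataset, small_split):
        cfg = FitConfig(n_enet_lambdas=20, enet_mixes=(0.1, 1.0))
        cands = elastic_net_candidates(small_dataset, small_split, 0, cfg)
        best = fit_elastic_net_grid(small_dataset, small_split, 0, cfg)
        assert best.validation_error <= min(c.validation_error for c in cands) + 1e-12


class TestPredict:
    def test_hand_sums(self):
        A = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]] * 6)
        ds = build_dataset(A + 0.0)
        # manual model without offsets: a plain weighted sum
        m = LinearROIModel(target_roi=0, predictors=[1, 2], weights=[2.0, -1.0], fit_method="ols")
        x = ds.activity[:, 1] * 2.0 - ds.activity[:, 2]
        np.testing.assert_allclose(predict(m, ds, (0, 12)), x)

    def test_zero_weights_give_zero_series(self, small_dataset):
        m = LinearROIModel(target_roi=0, predictors=[1, 2], weights=[0.0, 0.0], fit_method="ols")
        np.testing.assert_allclose(predict(m, small_dataset, (0, 10)), 0.0)

    def test_unknown_predictor_rejected(self, small_dataset):
        m = LinearROIModel(target_roi=0, predictors=[99], weights=[1.0], fit_method="ols")
        with pytest.raises(KeyError):
            predict(m, small_dataset, (0, 10))

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            LinearROIModel(target_roi=0, predictors=[], weights=[], fit_method="ols")
        with pytest.raises(ValueError):
            LinearROIModel(target_roi=0, predictors=[0, 1], weights=[1.0, 2.0], fit_method="ols")
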