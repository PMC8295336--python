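"""L1-logistic fitting, ROC/AUC, U tests, and cross-validation machinery."""

import numpy as np
import pytest

from bfmorph import discrim, synth
from bfmorph.discrim import CVConfig, DiscriminativeModel

from conftest import model_level_xy, scaled_cv_config


def _brute_force_auc(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLinearPredictor:
    def test_null_model(self):
        m = DiscriminativeModel(0.0, np.zeros(4), 0.1)
        eta, post = discrim.linear_predictor(m, np.ones(4))
        assert eta == 0.0 and post == 0.5

    def test_log_three_gives_three_quarters(self):
        m = DiscriminativeModel(np.log(3.0), np.zeros(2), 0.0)
        _, post = discrim.linear_predictor(m, np.zeros(2))
        assert post == pytest.approx(0.75)

    def test_posterior_monotone_in_eta(self):
        m = DiscriminativeModel(0.0, np.array([1.0]), 0.0)
        etas, posts = discrim.linear_predictor(
            m, np.linspace(-5, 5, 21).reshape(-1, 1)
        )
        assert np.all(np.diff(posts) > 0)

    def test_length_mismatch(self):
        m = DiscriminativeModel(0.0, np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            discrim.linear_predictor(m, np.zeros(4))


class TestFitL1Logistic:
    def test_above_lambda_max_null_model(self, toy_logistic_data):
        X, y = toy_logistic_data
        lmax = discrim.lambda_max(X, y)
        fit = discrim.fit_l1_logistic((X, y), lmax * 1.01)
        assert np.all(fit.model.beta == 0)
        assert fit.model.alpha == pytest.approx(np.log(y.mean() / (1 - y.mean())))

    def test_unpenalized_matches_newton_oracle(self, toy_logistic_data):
        sm = pytest.importorskip("statsmodels.api")
        X, y = toy_logistic_data
        fit = discrim.fit_l1_logistic((X, y), 0.0)
        ours = np.r_[fit.model.alpha, fit.model.beta]
        res = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.max(np.abs(ours - res.params)) < 1e-6

    def test_perfect_feature_gives_training_auc_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 3))
        y = (X[:, 1] > 0).astype(float)
        fit = discrim.fit_l1_logistic((X, y), 1e-4)
        _, _, auc = discrim.roc_auc(fit.model.decision(X), y)
        assert auc == 1.0

    def test_objective_trace_non_increasing(self, toy_logistic_data):
        X, y = toy_logistic_data
        for lam in (0.0, 0.01, 0.05):
            fit = discrim.fit_l1_logistic((X, y), lam)
            assert np.all(np.diff(fit.objective_trace) <= 1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            discrim.fit_l1_logistic((np.zeros((5, 2)), np.ones(5)), 0.1)

    def test_beta_shrinks_monotonically_to_zero(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        y = (rng.random(200) < 1 / (1 + np.exp(-1.5 * x))).astype(float)
        X = x.reshape(-1, 1)
        lams = np.linspace(0, discrim.lambda_max(X, y) * 1.05, 12)
        betas = [discrim.fit_l1_logistic((X, y), lam).model.beta[0] for lam in lams]
        assert betas[0] > 0 and betas[-1] == 0.0
        assert all(b2 <= b1 + 1e-8 for b1, b2 in zip(betas, betas[1:]))

    def test_model_json_round_trip(self, toy_logistic_data):
        X, y = toy_logistic_data
        model = discrim.fit_l1_logistic((X, y), 0.02).model
        clone = DiscriminativeModel.from_json(model.to_json())
        assert clone.alpha == model.alpha
        assert np.array_equal(clone.beta, model.beta)


class TestLambdaGrid:
    def test_grid_properties(self, toy_logistic_data):
        X, y = toy_logistic_data
        grid = discrim.lambda_grid((X, y), 30, 3.0)
        assert len(grid) == 30
        assert np.all(np.diff(grid) < 0)
        assert grid[0] == pytest.approx(discrim.lambda_max(X, y))
        fit = discrim.fit_l1_logistic((X, y), grid[0])
        assert np.all(fit.model.beta == 0)


class TestRocAuc:
    def test_hand_example_half(self):
        _, _, auc = discrim.roc_auc([0.9, 0.8, 0.3], [1, 0, 1])
        assert auc == 0.5

    def test_perfect_ranking(self):
        fpr, tpr, auc = discrim.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1

    def test_all_tied_scores(self):
        _, _, auc = discrim.roc_auc([0.5] * 6, [0, 1, 0, 1, 1, 0])
        assert auc == 0.5

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        fpr, tpr, _ = discrim.roc_auc(s, y)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            n = int(rng.integers(4, 20))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            _, _, auc = discrim.roc_auc(scores, labels)
            assert auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            discrim.roc_auc([0.1, 0.9], [1, 1])


class TestFeatureUTest:
    def test_exact_enumeration_example(self):
        u, p = discrim.feature_u_test([3, 4, 5], [0, 1, 2], "greater")
        assert u == 9.0
        assert p == pytest.approx(1 / 20)

    def test_identical_samples_tie_statistic(self):
        x = [1.0, 2.0, 3.0]
        u, _ = discrim.feature_u_test(x, x, "greater")
        assert u == pytest.approx(len(x) * len(x) / 2)

    def test_swap_relation_exact(self):
        x, y = [3.0, 5.0, 9.0], [1.0, 4.0, 7.0]
        u_xy, p_xy = discrim.feature_u_test(x, y, "greater")
        u_yx, p_yx = discrim.feature_u_test(y, x, "less")
        assert p_xy == pytest.approx(p_yx)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            discrim.feature_u_test([], [1.0])


class TestNestedCV:
    def test_fold_count_and_reporting(self):
        spec = synth.EffectSpec(shifted_indices=(0,), delta=(2.0,))
        X, y = model_level_xy(spec, 110, seed=5)
        res = discrim.nested_cv((X, y), scaled_cv_config(3, n_lambda=30))
        assert len(res.fold_aucs) == 10
        assert len(res.fold_curves) == 10
        assert len(res.selected_sets) == 10
        assert res.mean_auc == pytest.approx(res.fold_aucs.mean())

    def test_class_too_small_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 4))
        y = np.r_[np.zeros(15), np.ones(15)]
        with pytest.raises(ValueError, match="per class"):
            discrim.nested_cv((X, y), CVConfig(outer_folds=10, seed=0))

    def test_seeded_reproducibility(self):
        spec = synth.EffectSpec(shifted_indices=(1,), delta=(1.0,))
        X, y = model_level_xy(spec, 100, seed=6)
        cfg = scaled_cv_config(9, outer_folds=5, inner_folds=5, n_lambda=20)
        a = discrim.nested_cv((X, y), cfg)
        b = discrim.nested_cv((X, y), cfg)
        assert np.array_equal(a.fold_aucs, b.fold_aucs)
        assert np.array_equal(a.chosen_lambdas, b.chosen_lambdas)


class TestLearningCurve:
    def test_rows_and_monotone_trend(self):
        spec = synth.EffectSpec(shifted_indices=(0,), delta=(3.0,))
        X, y = model_level_xy(spec, 150, seed=2)
        cfg = scaled_cv_config(1, outer_folds=5, inner_folds=5, n_lambda=20)
        out = discrim.learning_curve((X, y), [0.4, 1.0], repeats=1, cfg=cfg)
        assert list(out.fraction) == [0.4, 1.0]
        assert out.mean_auc.iloc[1] >= out.mean_auc.iloc[0] - 0.02

    def test_too_small_fraction_skipped(self):
        spec = synth.EffectSpec()
        X, y = model_level_xy(spec, 60, seed=3)
        cfg = scaled_cv_config(1, outer_folds=10, inner_folds=5, n_lambda=10)
        with pytest.warns(UserWarning, match="skipped"):
            out = discrim.learning_curve((X, y), [0.05, 1.0], repeats=1, cfg=cfg)
        assert list(out.fraction) == [1.0]


class TestBaggedCoefficients:
    def test_bagged_support_contains_stable_signal(self):
        spec = synth.EffectSpec(shifted_indices=(4,), delta=(3.0,))
        X, y = model_level_xy(spec, 150, seed=8)
        cfg = scaled_cv_config(2, n_lambda=30)
        bagged, model = discrim.bagged_coefficients((X, y), cfg, n_boot=8)
        assert bagged.shape == (296,)
        assert bagged[4] > 0
        assert model.beta[4] > 0
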