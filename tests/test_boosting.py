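"""Second-order boosted trees: gradients, leaf weights, split search,
objective monotonicity, and equivalence with a reference implementation."""

import math

import numpy as np
import pytest
import xgboost as xgb

from epiwatch import boosting
from epiwatch.boosting import (
    TrainConfig,
    best_split,
    classify,
    leaf_weight,
    load_model,
    logistic_grad_hess,
    predict,
    predict_margin,
    save_model,
    train,
)


@pytest.fixture
def separable_toy():
    """8 points split cleanly on feature 0."""
    X = np.array(
        [[0.1, 5], [0.2, 1], [0.3, 7], [0.4, 2], [0.6, 3], [0.7, 8], [0.8, 4], [0.9, 6]],
        dtype=float,
    )
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return X, y


class TestGradHess:
    def test_label_one_at_zero_margin(self):
        g, h = logistic_grad_hess([1], [0.0])
        assert g[0] == pytest.approx(-0.5)
        assert h[0] == pytest.approx(0.25)

    def test_label_zero_at_zero_margin(self):
        g, h = logistic_grad_hess([0], [0.0])
        assert g[0] == pytest.approx(0.5)
        assert h[0] == pytest.approx(0.25)

    def test_hessian_positive_and_bounded(self):
        margins = np.linspace(-10, 10, 101)
        _, h = logistic_grad_hess(np.zeros(101), margins)
        assert (h > 0).all()
        assert (h <= 0.25 + 1e-12).all()

    def test_matches_finite_differences(self):
        """Oracle: numerically differentiate the logistic loss."""
        rng = np.random.default_rng(0)
        for y in (0.0, 1.0):
            m = rng.normal(size=5)
            g, h = logistic_grad_hess(np.full(5, y), m)

            def loss(mm):
                p = 1 / (1 + np.exp(-mm))
                return -(y * np.log(p) + (1 - y) * np.log(1 - p))

            eps = 1e-6
            g_num = (loss(m + eps) - loss(m - eps)) / (2 * eps)
            assert np.allclose(g, g_num, atol=1e-5)
            eps = 1e-4  # second difference needs a larger step for roundoff
            h_num = (loss(m + eps) - 2 * loss(m) + loss(m - eps)) / eps**2
            assert np.allclose(h, h_num, atol=1e-5)


class TestLeafWeight:
    def test_minimizes_per_leaf_quadratic(self):
        # analytic minimum of G*w + (1/2)(H+lambda)*w^2 at G=2,H=3,lambda=1
        assert leaf_weight(2, 3, 1) == pytest.approx(-0.5)

    def test_zero_gradient_gives_zero_weight(self):
        assert leaf_weight(0, 5, 1) == 0.0

    def test_large_lambda_shrinks_weight(self):
        assert abs(leaf_weight(2, 3, 1e9)) < 1e-8

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            leaf_weight(1, 0, 0)


class TestBestSplit:
    def test_opposite_gradients_split_between_them(self):
        X = np.array([[0.0], [1.0]])
        g = np.array([0.5, -0.5])
        h = np.array([0.25, 0.25])
        split = best_split(X, g, h, lambda_reg=0.0, gamma_reg=0.0)
        assert split is not None
        feat, thr, gain = split
        assert feat == 0
        assert thr == pytest.approx(0.5)
        # oracle: enumerate the only candidate split by hand
        want = 0.5 * (0.25 / 0.25 + 0.25 / 0.25 - 0.0 / 0.5)
        assert gain == pytest.approx(want)

    def test_gamma_above_any_gain_prunes(self):
        X = np.array([[0.0], [1.0]])
        g = np.array([0.5, -0.5])
        h = np.array([0.25, 0.25])
        assert best_split(X, g, h, 0.0, gamma_reg=100.0) is None

    def test_constant_features_cannot_split(self):
        X = np.ones((4, 3))
        g = np.array([0.5, -0.5, 0.5, -0.5])
        h = np.full(4, 0.25)
        assert best_split(X, g, h, 1.0, 0.0) is None

    def test_matches_exhaustive_enumeration(self):
        """Oracle: brute-force every (feature, boundary) candidate."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        g = rng.normal(size=20)
        h = rng.uniform(0.01, 0.25, size=20)
        lam, gamma = 1.0, 0.1
        best_gain = -np.inf
        for j in range(3):
            xs = np.unique(X[:, j])
            for a, b in zip(xs, xs[1:]):
                thr = (a + b) / 2
                m = X[:, j] <= thr
                gl, hl = g[m].sum(), h[m].sum()
                gr, hr = g[~m].sum(), h[~m].sum()
                gain = 0.5 * (
                    gl**2 / (hl + lam)
                    + gr**2 / (hr + lam)
                    - (gl + gr) ** 2 / (hl + hr + lam)
                ) - gamma
                best_gain = max(best_gain, gain)
        split = best_split(X, g, h, lam, gamma)
        assert split is not None
        assert split[2] == pytest.approx(best_gain)


class TestTrain:
    def test_separable_toy_reaches_perfect_training_accuracy(self, separable_toy):
        X, y = separable_toy
        model = train(X, y, TrainConfig(n_rounds=10, max_depth=2, seed=0))
        pred = (predict(model, X) >= 0.5).astype(int)
        assert (pred == y).all()

    def test_zero_rounds_predicts_base_rate(self, separable_toy):
        X, y = separable_toy
        model = train(X, y, TrainConfig(n_rounds=0))
        assert np.allclose(predict(model, X), y.mean())

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            train(X, np.ones(4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_non_increasing_each_round(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        model = train(X, y, TrainConfig(n_rounds=20, seed=seed))
        trace = model.objective_trace
        assert len(trace) == 21
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_leaf_weights_match_closed_form_posthoc(self):
        """Recompute -G/(H+lambda) by re-routing samples through each tree."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(int)
        cfg = TrainConfig(n_rounds=5, learning_rate=1.0, max_depth=2, lambda_reg=1.0)
        model = train(X, y, cfg)
        margins = np.full(30, model.base_score)
        for tree in model.trees:
            g, h = logistic_grad_hess(y, margins)

            def check(node, idx):
                if node.is_leaf:
                    want = cfg.learning_rate * leaf_weight(
                        g[idx].sum(), h[idx].sum(), cfg.lambda_reg
                    )
                    assert node.weight == pytest.approx(want)
                    return
                m = X[idx, node.feature] <= node.threshold
                check(node.left, idx[m])
                check(node.right, idx[~m])

            check(tree, np.arange(30))
            margins = margins + boosting._tree_predict(tree, X)

    def test_importance_nonnegative_and_on_informative_feature(self, separable_toy):
        X, y = separable_toy
        model = train(X, y, TrainConfig(n_rounds=5, max_depth=2))
        imp = model.feature_importance()
        assert all(v >= 0 for v in imp.values())
        assert imp.get(0, 0) > imp.get(1, 0)


class TestReferenceEquivalence:
    @pytest.mark.parametrize("seed,depth,rounds", [(42, 3, 10), (7, 2, 25), (11, 4, 5)])
    def test_margins_match_xgboost_exact_greedy(self, seed, depth, rounds):
        rng = np.random.default_rng(seed)
        n = 50
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=n) > 0).astype(int)
        cfg = TrainConfig(
            n_rounds=rounds, learning_rate=0.3, max_depth=depth,
            lambda_reg=1.0, gamma_reg=0.0, min_child_hessian=0.0, base_score=0.0,
        )
        ours = predict_margin(train(X, y, cfg), X)
        ref = xgb.XGBClassifier(
            n_estimators=rounds, learning_rate=0.3, max_depth=depth,
            reg_lambda=1.0, gamma=0.0, min_child_weight=0.0, base_score=0.5,
            tree_method="exact", objective="binary:logistic", n_jobs=1,
        )
        ref.fit(X, y)
        theirs = ref.predict(X, output_margin=True)
        # reference stores leaf weights in float32: allow its own precision
        assert np.allclose(ours, theirs, rtol=1e-6, atol=1e-6)


class TestPredictClassify:
    def test_empty_model_predicts_sigmoid_base(self, separable_toy):
        X, y = separable_toy
        model = train(X, y, TrainConfig(n_rounds=0, base_score=0.3))
        assert np.allclose(predict(model, X), 1 / (1 + math.exp(-0.3)))

    def test_feature_dimension_mismatch_rejected(self, separable_toy):
        X, y = separable_toy
        model = train(X, y, TrainConfig(n_rounds=1))
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 5)))

    def test_tie_at_threshold_is_false_info(self):
        assert classify([0.5, 0.49], 0.5) == ["false_info", "true_info"]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_threshold_open_interval(self, bad):
        with pytest.raises(ValueError):
            classify([0.5], bad)

    def test_round_trip_persistence(self, tmp_path, separable_toy):
        X, y = separable_toy
        model = train(X, y, TrainConfig(n_rounds=5, max_depth=2))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.allclose(predict(back, X), predict(model, X))
        assert back.config == model.config
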