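import itertools

import numpy as np
import pytest

from histoclust import (
    BENIGN,
    MALIGNANT,
    SvmHead,
    TrainConfig,
    build_model1,
    fit_linear_svm,
    fit_svm_head,
    predict,
    train_softmax,
)
from histoclust.data import LabeledDataset
from histoclust.heads import _hinge_loss_and_grad, train_hinge
from histoclust.nncore import svm_objective


class TestTrainConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [{"epochs": -1}, {"batch_size": 0}, {"learning_rate": 0.0}, {"svm_c": 0.0}],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


class TestSoftmaxTraining:
    def test_zero_epochs_returns_net_unchanged(self, separable_ds, rng):
        from histoclust import stratified_split

        tr, te = stratified_split(separable_ds, 0.3, seed=0)
        net = build_model1(conv_maps=(4, 4, 4, 4, 16), seed=1)
        before = [p.copy() for _, _, p in net.parameters()]
        net, history = train_softmax(net, tr, te, TrainConfig(epochs=0))
        assert len(history) == 0
        for (_, _, p), b in zip(net.parameters(), before):
            assert np.array_equal(p, b)

    def test_learns_the_separable_task(self, trained_small):
        net, history, train_ds, test_ds = trained_small
        assert history.train_acc[-1] >= 95.0
        assert history.test_acc[-1] >= 90.0

    def test_history_has_all_curves(self, trained_small):
        _, history, _, _ = trained_small
        df = history.to_dataframe()
        assert list(df.columns) == [
            "epoch", "train_acc", "test_acc",
            "train_loss", "test_loss", "train_mcc", "test_mcc",
        ]
        assert len(df) == 15

    def test_loss_trend_decreasing_on_separable_task(self, trained_small):
        """Smoothed training loss decreases from start to finish."""
        _, history, _, _ = trained_small
        loss = np.asarray(history.train_loss)
        k = 3
        smoothed = np.convolve(loss, np.ones(k) / k, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_same_seed_gives_identical_history(self, separable_ds):
        from histoclust import stratified_split

        tr, te = stratified_split(separable_ds, 0.3, seed=0)
        histories = []
        for _ in range(2):
            net = build_model1(conv_maps=(4, 4, 4, 4, 16), seed=9)
            _, h = train_softmax(net, tr, te, TrainConfig(epochs=2, seed=13))
            histories.append(h)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].test_acc == histories[1].test_acc

    def test_divergence_aborts_with_diagnostic(self, separable_ds):
        from histoclust import stratified_split

        tr, te = stratified_split(separable_ds, 0.3, seed=0)
        net = build_model1(conv_maps=(4, 4, 4, 4, 16), seed=2)
        # blow up the decision weights so the first loss overflows to inf
        net.layers[-1].params["W"] += 1e6
        net.layers[-1].params["b"] += np.array([1e308, -1e308])
        with pytest.raises(FloatingPointError, match="diverged"):
            train_softmax(net, tr, te, TrainConfig(epochs=1, seed=0))


class TestHingeTraining:
    def test_hinge_gradient_matches_finite_difference(self, rng):
        scores = rng.normal(size=(6, 2))
        y = rng.integers(0, 2, size=6)
        loss, grad = _hinge_loss_and_grad(scores, y)
        eps = 1e-7
        for i, j in itertools.product(range(6), range(2)):
            s = scores.copy()
            s[i, j] += eps
            lp, _ = _hinge_loss_and_grad(s, y)
            s[i, j] -= 2 * eps
            lm, _ = _hinge_loss_and_grad(s, y)
            assert (lp - lm) / (2 * eps) == pytest.approx(grad[i, j], abs=1e-6)

    def test_end_to_end_hinge_learns(self, separable_ds):
        from histoclust import stratified_split

        tr, te = stratified_split(separable_ds, 0.3, seed=0)
        net = build_model1(conv_maps=(4, 4, 4, 4, 16), seed=3)
        net, history = train_hinge(
            net, tr, te, TrainConfig(epochs=15, learning_rate=3e-3, seed=4)
        )
        assert history.train_acc[-1] >= 90.0


class TestSvmHead:
    def test_toy_problem_matches_grid_search_oracle(self):
        """2-D toy set: the fitted boundary must match direct minimization
        of the hinge objective over a weight grid."""
        x = np.tile([[0.0, 1.0], [0.0, -1.0]], (20, 1))
        y = np.tile([MALIGNANT, BENIGN], 20)
        head = fit_linear_svm(x, y, c=1.0)
        # brute-force: minimize the objective over a grid of weight vectors
        grid = np.linspace(-3, 3, 121)
        best_w, best_obj = None, np.inf
        y_signed = np.where(y == MALIGNANT, 1, -1)
        for w1, w2 in itertools.product(grid, grid):
            obj = svm_objective(np.array([w1, w2]), x, y_signed, c=1.0)
            if obj < best_obj:
                best_w, best_obj = np.array([w1, w2]), obj
        assert best_w == pytest.approx([0.0, 1.0], abs=1e-9)
        fitted_obj = svm_objective(head.w, x, y_signed, c=1.0)
        assert fitted_obj == pytest.approx(best_obj, rel=1e-3)
        assert np.array_equal(head.predict(x), y)

    def test_fitted_objective_no_worse_than_zero_weights(self, trained_small):
        net, _, train_ds, _ = trained_small
        head = fit_svm_head(net, train_ds, c=1.0)
        feats = net.penultimate_features(train_ds.images)
        y_signed = np.where(train_ds.labels == MALIGNANT, 1, -1)
        fitted = svm_objective(head.w, feats, y_signed, c=1.0)
        at_zero = svm_objective(np.zeros_like(head.w), feats, y_signed, c=1.0)
        assert fitted <= at_zero + 1e-9
        assert at_zero == pytest.approx(1.0 * len(train_ds))

    def test_small_c_shrinks_weights_and_margins_to_zero(self):
        """As C -> 0 regularization dominates: W -> 0 and every margin
        collapses toward the tie point (where the rule predicts benign)."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 3))
        y = (x[:, 0] > 0).astype(int)
        big = fit_linear_svm(x, y, c=10.0)
        tiny = fit_linear_svm(x, y, c=1e-6)
        assert np.linalg.norm(tiny.w) < 1e-3 < np.linalg.norm(big.w)
        assert np.abs(tiny.margin(x)).max() < 1e-3

    def test_single_class_rejected(self, trained_small):
        net, _, train_ds, _ = trained_small
        ones = LabeledDataset(train_ds.images[:4], np.ones(4, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            fit_svm_head(net, ones)

    def test_head_accuracy_on_separable_features(self, trained_small):
        net, history, train_ds, _ = trained_small
        head = fit_svm_head(net, train_ds)
        preds = head.predict(net.penultimate_features(train_ds.images))
        acc = 100.0 * np.mean(preds == train_ds.labels)
        assert acc >= history.train_acc[-1] - 1e-9


class TestPredict:
    def test_softmax_tie_breaks_to_benign(self):
        net = build_model1(conv_maps=(4, 4, 4, 4, 16), seed=0)
        # zero decision layer: both scores identical for any input
        net.layers[-1].params["W"][...] = 0.0
        net.layers[-1].params["b"][...] = 0.0
        x = np.random.default_rng(0).random((3, 32, 32, 3))
        assert (predict(net, x, head="softmax") == BENIGN).all()

    def test_svm_zero_margin_is_benign(self):
        head = SvmHead(w=np.zeros(4), b=0.0, c=1.0)
        feats = np.ones((5, 4))
        assert (head.predict(feats) == BENIGN).all()

    def test_strong_malignant_scores_predict_malignant(self):
        net = build_model1(conv_maps=(4, 4, 4, 4, 16), seed=0)
        net.layers[-1].params["W"][...] = 0.0
        net.layers[-1].params["b"][...] = [0.0, 10.0]
        x = np.random.default_rng(1).random((2, 32, 32, 3))
        assert (predict(net, x, head="softmax") == MALIGNANT).all()

    def test_prediction_is_total_and_binary(self, trained_small, rng):
        net, _, _, test_ds = trained_small
        preds = predict(net, test_ds.images, head="softmax")
        assert preds.shape == (len(test_ds),)
        assert set(np.unique(preds)) <= {BENIGN, MALIGNANT}

    def test_unknown_head_rejected(self, trained_small):
        net, _, _, test_ds = trained_small
        with pytest.raises(ValueError):
            predict(net, test_ds.images, head="mystery")
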