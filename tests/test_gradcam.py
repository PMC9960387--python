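"""Grad-CAM attribution and the slope-masked class-importance score."""

import numpy as np
import pytest

from edapain.gradcam import (SaliencyMap, dataset_slope_importance, gradcam,
                             slope_masks, window_slope_weights)
from edapain.neural import TrainConfig, build_cnn, build_mlp, train_classifier


@pytest.fixture(scope="module")
def tiny_cnn():
    return build_cnn(128, filters=(4, 6, 8), kernel=5, pool=4, dropout=0.0,
                     seed=3)


class TestGradcam:
    def test_saliency_nonnegative_and_upsampled(self, tiny_cnn, rng):
        x = rng.normal(0.5, 0.2, 128)
        for c in (0, 1):
            s = gradcam(tiny_cnn, x, c)
            assert np.all(s.raw >= 0)
            assert s.upsampled.size == 128
            assert np.all(s.upsampled >= 0)

    def test_gradient_matches_finite_differences(self, tiny_cnn, rng):
        """Central finite differences on the class score through the network
        tail must match the analytic feature-map gradient (away from
        max-pooling ties)."""
        x = rng.normal(0.5, 0.2, (1, 128, 1))
        fmap, grad = tiny_cnn.class_score_gradient(x, 1)
        eps = 1e-4
        pool = 4
        n, t, c = fmap.shape
        checked = 0
        for ti in range(t):
            for ci in range(c):
                block = fmap[0, (ti // pool) * pool:(ti // pool + 1) * pool, ci]
                top2 = np.sort(block)[-2:]
                if top2[1] - top2[0] < 10 * eps:
                    continue  # pooling tie: subgradient ambiguity expected
                fp = fmap.copy()
                fp[0, ti, ci] += eps
                fm = fmap.copy()
                fm[0, ti, ci] -= eps
                yp = tiny_cnn.forward_from(tiny_cnn.conv_hook, fp)[0, 1]
                ym = tiny_cnn.forward_from(tiny_cnn.conv_hook, fm)[0, 1]
                fd = (yp - ym) / (2 * eps)
                assert grad[0, ti, ci] == pytest.approx(fd, rel=1e-3, abs=1e-8)
                checked += 1
        assert checked >= 20

    def test_model_without_conv_rejected(self, rng):
        mlp = build_mlp(32, seed=0)
        with pytest.raises(ValueError, match="convolutional"):
            gradcam(mlp, rng.normal(size=32), 0)


class TestSlopeMasks:
    def test_strictly_increasing(self):
        g_plus, g_minus = slope_masks(np.arange(1.0, 6.0))
        assert g_plus.tolist() == [0, 1, 1, 1, 1]
        assert g_minus.tolist() == [1, 0, 0, 0, 0]

    def test_strictly_decreasing(self):
        g_plus, _ = slope_masks(np.arange(5.0, 0.0, -1.0))
        assert np.all(g_plus == 0)

    def test_worked_example(self):
        g_plus, g_minus = slope_masks(np.array([0.0, 1.0, 0.5, 0.7]))
        assert g_plus.tolist() == [0, 1, 0, 1]
        assert g_minus.tolist() == [1, 0, 1, 0]

    def test_masks_partition_all_positions(self, rng):
        for _ in range(100):
            v = rng.normal(size=rng.integers(1, 60))
            g_plus, g_minus = slope_masks(v)
            assert np.array_equal(g_plus + g_minus, np.ones(v.size))


def _map(scores):
    scores = np.asarray(scores, float)
    return SaliencyMap(raw=scores, upsampled=scores, class_idx=1)


class TestSlopeWeights:
    def test_four_point_worked_example(self):
        sal = _map([0.2, 0.4, 0.1, 0.3])
        wp, wm = window_slope_weights(sal, slope_masks(np.array([0, 1, 0.5, 0.7])))
        assert wp == pytest.approx(0.7)
        assert wm == pytest.approx(0.3)

    def test_uniform_saliency_on_increasing_window(self):
        sal = _map(np.ones(5))
        wp, wm = window_slope_weights(sal, slope_masks(np.arange(1.0, 6.0)))
        assert (wp, wm) == (4.0, 1.0)
        assert wp / (wp + wm) == pytest.approx(0.8)

    def test_zero_saliency(self):
        sal = _map(np.zeros(6))
        wp, wm = window_slope_weights(sal, slope_masks(np.arange(6.0)))
        assert (wp, wm) == (0.0, 0.0)

    def test_sum_equals_total_saliency(self, rng):
        for _ in range(50):
            v = rng.normal(size=20)
            s = np.abs(rng.normal(size=20))
            wp, wm = window_slope_weights(_map(s), slope_masks(v))
            assert wp + wm == pytest.approx(s.sum(), abs=1e-10)

    def test_positive_rescaling_leaves_normalised_weights(self, rng):
        v = rng.normal(size=30)
        s = np.abs(rng.normal(size=30))
        wp, wm = window_slope_weights(_map(s), slope_masks(v))
        wp2, wm2 = window_slope_weights(_map(s * 37.5), slope_masks(v))
        assert wp / (wp + wm) == pytest.approx(wp2 / (wp2 + wm2), abs=1e-12)

    def test_time_reversal_swaps_roles_up_to_boundary(self, rng):
        # uniform saliency is symmetric under reversal; tie-free values
        v = rng.normal(size=41)
        s = np.ones(41)
        wp, wm = window_slope_weights(_map(s), slope_masks(v))
        wp_r, wm_r = window_slope_weights(_map(s), slope_masks(v[::-1]))
        assert wp_r == pytest.approx(wm - 1)
        assert wm_r == pytest.approx(wp + 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            window_slope_weights(_map(np.ones(4)), slope_masks(np.ones(5)))


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    n, length = 64, 128
    y = np.arange(n) % 2
    x = rng.normal(0.3, 0.02, size=(n, length))
    x[y == 1] += np.linspace(0, 0.5, length)[None, :]
    x[y == 0] += np.linspace(0.5, 0, length)[None, :]
    model = build_cnn(length, filters=(4, 6, 8), kernel=5, pool=4,
                      dropout=0.0, seed=1)
    train_classifier(model, x[:, :, None], y,
                     TrainConfig(epochs=30, learning_rate=1e-3, seed=0))
    return model, x, y


class TestDatasetSlopeImportance:

    def test_normalised_weights_sum_to_one(self, trained):
        model, x, y = trained
        r = dataset_slope_importance(model, x, 1)
        assert r.w_plus_norm + r.w_minus_norm == pytest.approx(1.0)
        assert r.w_plus >= 0 and r.w_minus >= 0

    def test_modes(self, trained):
        model, x, y = trained
        r_all = dataset_slope_importance(model, x, 1, mode="all")
        r_pred = dataset_slope_importance(model, x, 1, mode="predicted")
        r_corr = dataset_slope_importance(model, x, 1, mode="correct",
                                          true_labels=y)
        assert r_all.n_windows == x.shape[0]
        assert r_corr.n_windows <= r_pred.n_windows <= r_all.n_windows

    def test_correct_mode_requires_labels(self, trained):
        model, x, _ = trained
        with pytest.raises(ValueError):
            dataset_slope_importance(model, x, 1, mode="correct")

    def test_zero_saliency_reported_missing_with_warning(self):
        model = build_cnn(128, filters=(4, 4, 4), kernel=5, pool=4,
                          dropout=0.0, seed=0)
        # force the head to make class-1 saliency impossible
        model.layers[-1].W[...] = 0.0
        model.layers[-1].W[:, 0] = 1.0
        x = np.abs(np.random.default_rng(0).normal(0.5, 0.1, (4, 128)))
        with pytest.warns(UserWarning, match="zero"):
            r = dataset_slope_importance(model, x, 1, mode="all")
        assert r.w_plus_norm is None and r.w_minus_norm is None
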