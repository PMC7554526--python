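"""U-net construction, training regime, inference contracts."""

import numpy as np
import pytest

from wmlseg.errors import ConfigurationError, GeometryError, NoDataError
from wmlseg.model import NetConfig, TrainConfig, UNetSegmenter, build_network, predict, train
from wmlseg import _nn


def _blob_dataset(n_slices, side, rng, frac_bright=0.06):
    """Bright square blobs on noisy background; mask = blob."""
    imgs = np.zeros((n_slices, 1, side, side), dtype=np.float32)
    masks = np.zeros((n_slices, side, side), dtype=np.float32)
    half = max(2, int(side * np.sqrt(frac_bright) / 2))
    for i in range(n_slices):
        r, c = rng.integers(half, side - half, size=2)
        imgs[i, 0] = rng.normal(90, 10, (side, side))
        imgs[i, 0, r - half : r + half, c - half : c + half] = rng.normal(200, 10, (2 * half, 2 * half))
        masks[i, r - half : r + half, c - half : c + half] = 1.0
    return imgs, masks


class TestBuild:
    @pytest.mark.parametrize("in_channels", [1, 2])
    def test_forward_shape_and_range(self, in_channels, rng):
        net = build_network(NetConfig(in_channels=in_channels, depth=2, base_filters=4), seed=0)
        x = rng.normal(size=(3, in_channels, 64, 64)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.shape == (3, 64, 64)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_indivisible_side_raises(self, rng):
        net = build_network(NetConfig(depth=2), seed=0)
        with pytest.raises(GeometryError):
            net.predict_proba(rng.normal(size=(1, 1, 30, 30)).astype(np.float32))

    def test_parameter_count_deterministic_in_config(self):
        a = build_network(NetConfig(1, 2, 8), seed=0)
        b = build_network(NetConfig(1, 2, 8), seed=99)
        assert a.n_parameters == b.n_parameters
        bigger = build_network(NetConfig(1, 2, 16), seed=0)
        assert bigger.n_parameters > a.n_parameters

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            NetConfig(in_channels=3)
        with pytest.raises(ConfigurationError):
            TrainConfig(learning_rate=-1)

    def test_gradients_match_finite_differences(self, rng):
        """Backprop through the full encoder-decoder agrees with numeric grads."""
        net = build_network(NetConfig(in_channels=2, depth=2, base_filters=2), seed=0)
        x = rng.normal(size=(2, 2, 8, 8)).astype(np.float32)
        y = (rng.random((2, 8, 8)) > 0.7).astype(np.float32)

        def loss():
            logits = net.forward_logits(x, train=True)
            return _nn.bce_with_logits(logits, y)

        l0, g = loss()
        for _, gr in net.params:
            gr[...] = 0.0
        net.backward(g)
        check = np.random.default_rng(2)
        for k in check.choice(len(net.params), 5, replace=False):
            p, gr = net.params[k]
            idx = tuple(check.integers(0, s) for s in p.shape)
            eps, old = 1e-3, p[idx]
            p[idx] = old + eps
            lp, _ = loss()
            p[idx] = old - eps
            lm, _ = loss()
            p[idx] = old
            # float32 forward passes limit finite-difference accuracy;
            # a structural backprop bug would be off by far more than 15%
            assert (lp - lm) / (2 * eps) == pytest.approx(gr[idx], rel=0.15, abs=1e-3)


class TestTrain:
    def test_empty_training_set_raises(self):
        net = build_network(NetConfig(depth=1, base_filters=2))
        with pytest.raises(NoDataError):
            train(net, np.zeros((0, 1, 16, 16)), np.zeros((0, 16, 16)), TrainConfig(epochs=1))

    def test_single_epoch_history_length(self, rng):
        imgs, masks = _blob_dataset(4, 16, rng)
        net = build_network(NetConfig(depth=1, base_filters=2))
        hist = train(net, imgs, masks, TrainConfig(epochs=1, seed=0))
        assert len(hist) == 1

    def test_loss_decreases_on_learnable_data(self, rng):
        imgs, masks = _blob_dataset(24, 32, rng)
        net = build_network(NetConfig(depth=2, base_filters=4), seed=0)
        hist = train(net, imgs, masks, TrainConfig(epochs=8, seed=0))
        assert hist[-1] < hist[0]

    def test_seeded_training_reproducible(self, rng):
        imgs, masks = _blob_dataset(8, 16, rng)
        hists = []
        for _ in range(2):
            net = build_network(NetConfig(depth=1, base_filters=2), seed=3)
            hists.append(train(net, imgs, masks, TrainConfig(epochs=3, seed=3)))
        assert hists[0] == hists[1]

    def test_overfit_capacity_on_ten_slices(self, rng):
        """The net can drive training DSC > 0.9 on a 10-slice set."""
        imgs, masks = _blob_dataset(10, 32, rng)
        net = build_network(NetConfig(depth=2, base_filters=8), seed=1)
        train(net, imgs, masks, TrainConfig(epochs=60, seed=1))
        pred = predict(net, imgs) > 0.5
        inter = (pred & masks.astype(bool)).sum()
        dsc = 2 * inter / (pred.sum() + masks.sum())
        assert dsc > 0.9


class TestPredict:
    def test_inference_deterministic(self, rng):
        net = build_network(NetConfig(depth=1, base_filters=2), seed=0)
        x = rng.normal(size=(4, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(predict(net, x), predict(net, x))

    def test_probabilities_in_unit_interval(self, rng):
        net = build_network(NetConfig(depth=1, base_filters=2), seed=0)
        for _ in range(10):
            p = predict(net, rng.normal(0, 300, size=(2, 1, 16, 16)).astype(np.float32))
            assert p.min() >= 0.0 and p.max() <= 1.0

    def test_channel_mismatch_raises(self, rng):
        net = build_network(NetConfig(in_channels=2, depth=1, base_filters=2))
        with pytest.raises(ConfigurationError):
            predict(net, rng.normal(size=(2, 1, 16, 16)).astype(np.float32))

    def test_background_slice_scores_low_after_training(self, rng):
        imgs, masks = _blob_dataset(16, 32, rng)
        net = build_network(NetConfig(depth=2, base_filters=4), seed=0)
        train(net, imgs, masks, TrainConfig(epochs=10, seed=0))
        bg = rng.normal(90, 10, size=(1, 1, 32, 32)).astype(np.float32)
        assert predict(net, bg).mean() < 0.5


def test_estimator_interface(rng):
    imgs, masks = _blob_dataset(8, 16, rng)
    est = UNetSegmenter(depth=1, base_filters=2, epochs=2, seed=0)
    assert est.get_params()["depth"] == 1
    est.fit(imgs, masks)
    assert len(est.loss_history_) == 2
    assert est.predict(imgs).dtype == bool

    from sklearn.base import clone

    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
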