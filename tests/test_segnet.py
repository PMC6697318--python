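"""U-Net segmenter: architecture invariants, training behavior, estimator API.

The receptive-field probe is validated against a perturbation oracle on a
real (tiny) network rather than a closed-form formula: the formulaic RF is an
upper bound that ignores pooling-block alignment, while the probe and the
oracle both track exact pixel influence.
"""

import dataclasses

import numpy as np
import pytest
from sklearn.base import clone

from octoseg import nn
from octoseg.compartments import lines_to_mask
from octoseg.segnet import (
    NetConfig,
    TrainConfig,
    UNet,
    UNetSegmenter,
    build_network,
    covers_input,
    receptive_field_support,
    train,
)
from octoseg.types import LabelMask, ValidationError

TINY = NetConfig(input_size=16, depth_levels=2, base_channels=2, convs_per_level=2, seed=0)


class TestConfigs:
    def test_input_size_must_match_depth(self):
        with pytest.raises(ValidationError, match="divisible"):
            NetConfig(input_size=100, depth_levels=6)

    def test_exactly_four_classes(self):
        with pytest.raises(ValidationError, match="4 classes"):
            NetConfig(input_size=512, n_classes=3)

    def test_training_recipe_validation(self):
        with pytest.raises(ValidationError):
            TrainConfig(learning_rate=0.0)


class TestUNet:
    def test_logit_shape(self):
        net = build_network(TINY)
        x = np.random.default_rng(0).random((3, 16, 16, 1)).astype(np.float32)
        logits = net.forward(x, train=False)
        assert logits.shape == (3, 16, 16, 4)

    def test_parameter_count_matches_hand_computed_formula(self):
        # depth 2, base 2, 2 convs/level:
        # enc0: conv(1->2): 9*1*2+2=20, conv(2->2): 9*2*2+2=38
        # enc1: conv(2->4): 9*2*4+4=76, conv(4->4): 9*4*4+4=148
        # up(4->2): 4*2*4+2=34; dec0: conv(4->2): 9*4*2+2=74, conv(2->2)=38
        # head 1x1 (2->4): 2*4+4=12
        assert build_network(TINY).n_parameters() == 20 + 38 + 76 + 148 + 34 + 74 + 38 + 12

    def test_initial_loss_near_log_n_classes(self):
        net = build_network(TINY)
        rng = np.random.default_rng(1)
        x = rng.random((4, 16, 16, 1)).astype(np.float32)
        y = rng.integers(0, 4, (4, 16, 16))
        loss, _ = nn.softmax_cross_entropy(net.forward(x, train=False), y)
        assert loss == pytest.approx(np.log(4.0), abs=0.15)

    def test_whole_network_gradients_match_central_differences(self):
        cfg = dataclasses.replace(TINY, input_size=8)
        net = build_network(cfg)
        rng = np.random.default_rng(42)
        for layer in net._layers():
            if hasattr(layer, "W"):
                layer.W = layer.W.astype(np.float64)
                # small random biases keep pre-activations away from the exact
                # ReLU kink, where numeric differences are undefined
                layer.b = layer.b.astype(np.float64) + rng.normal(0, 0.05, layer.b.shape)
                layer.dW = np.zeros_like(layer.W)
                layer.db = np.zeros_like(layer.b)
        x = np.random.default_rng(0).random((2, 8, 8, 1))
        y = np.random.default_rng(1).integers(0, 4, (2, 8, 8))

        def loss():
            return nn.softmax_cross_entropy(net.forward(x, train=False), y)[0]

        _, dlog = nn.softmax_cross_entropy(net.forward(x, train=True), y)
        net.backward(dlog.astype(np.float64))
        eps = 1e-6
        check_rng = np.random.default_rng(3)
        for p, g in net.params():
            for fi in check_rng.choice(p.size, size=min(p.size, 4), replace=False):
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                # rel tolerance limited by the float32 cast of the loss gradient
                assert num == pytest.approx(g[idx], rel=2e-3, abs=1e-7)


def _tiny_training_set(n=2):
    from octoseg.phantom import PhantomConfig, generate_phantoms

    cfg = PhantomConfig(
        width_px=32, height_px=32, n_images=n,
        boundary_wave_amplitude_px=0.5, cc_band_px=1, speckle_shape=30.0, seed=21,
    )
    pairs = generate_phantoms(cfg)
    X = [s for s, _ in pairs]
    y = [lines_to_mask(b, 32, 32) for _, b in pairs]
    return X, y


class TestUNetSegmenter:
    def _small_model(self, **kw):
        defaults = dict(
            input_size=32, depth_levels=3, base_channels=4, convs_per_level=2,
            learning_rate=2e-3, batch_size=2, epochs=150, seed=0,
        )
        defaults.update(kw)
        return UNetSegmenter(**defaults)

    def test_overfits_two_images(self):
        X, y = _tiny_training_set(2)
        model = self._small_model().fit(X, y)
        assert model.history_["train_loss"][-1] < 0.2 * model.history_["train_loss"][0]
        assert model.score(X, y) >= 0.9

    def test_fit_is_deterministic(self):
        X, y = _tiny_training_set(2)
        a = self._small_model(epochs=3).fit(X, y)
        b = self._small_model(epochs=3).fit(X, y)
        assert a.history_ == b.history_
        np.testing.assert_array_equal(
            a.predict(X)[0].labels, b.predict(X)[0].labels
        )

    def test_validation_history_and_early_stopping(self):
        X, y = _tiny_training_set(4)
        model = self._small_model(epochs=30, patience=2).fit(
            X[:2], y[:2], validation_data=(X[2:], y[2:])
        )
        assert model.n_epochs_run_ <= 30
        assert len(model.history_["val_loss"]) == model.n_epochs_run_

    def test_predict_resizes_back_to_original_geometry(self):
        X, y = _tiny_training_set(2)
        model = self._small_model(epochs=1).fit(X, y)
        from octoseg.types import BScan

        odd = BScan(pixels=np.random.default_rng(0).random((45, 37)))
        pred = model.predict([odd])[0]
        assert pred.labels.shape == (45, 37)

    def test_all_equal_logits_tie_breaks_to_lowest_class(self):
        model = self._small_model()
        model.net_ = build_network(model._net_config())
        for layer in model.net_._layers():
            if hasattr(layer, "W"):
                layer.W[...] = 0.0
                layer.b[...] = 0.0
        X, _ = _tiny_training_set(1)
        pred = model.predict(X)[0]
        assert (pred.labels == 0).all()  # vitreous = lowest class index

    def test_warns_when_a_class_is_absent(self):
        X, _ = _tiny_training_set(2)
        y = [LabelMask(labels=np.zeros((32, 32), dtype=int)) for _ in X]
        with pytest.warns(UserWarning, match="absent"):
            self._small_model(epochs=1).fit(X, y)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            self._small_model().fit([], [])

    def test_sklearn_param_plumbing_and_clone(self):
        model = self._small_model(learning_rate=1e-3)
        assert model.get_params()["learning_rate"] == 1e-3
        cl = clone(model)
        assert cl.get_params() == model.get_params()
        model.set_params(epochs=7)
        assert model.epochs == 7

    def test_save_load_round_trip(self, tmp_path):
        X, y = _tiny_training_set(2)
        model = self._small_model(epochs=2).fit(X, y)
        path = tmp_path / "model.pkl"
        model.save(path)
        assert path.with_suffix(".pkl.json").exists()
        loaded = UNetSegmenter.load(path)
        np.testing.assert_array_equal(
            loaded.predict(X)[0].labels, model.predict(X)[0].labels
        )

    def test_functional_train_wrapper(self):
        X, y = _tiny_training_set(3)
        pairs = list(zip(X, y))
        cfg = NetConfig(input_size=32, depth_levels=3, base_channels=4,
                        convs_per_level=2, seed=0)
        model, history = train(
            cfg, pairs[:2], pairs[2:], TrainConfig(learning_rate=1e-3, epochs=2)
        )
        assert model.n_epochs_run_ == 2
        assert len(history["val_loss"]) == 2


class TestReceptiveField:
    def _measured_support(self, cfg: NetConfig) -> np.ndarray:
        """Oracle: perturb each input pixel, watch the center output logit.

        All weights are made positive and biases slightly positive so no
        influence is lost to ReLU dead zones or cancellation.
        """
        net = build_network(cfg)
        for layer in net._layers():
            if hasattr(layer, "W"):
                layer.W = np.abs(layer.W) + 0.01
                layer.b = layer.b + 0.05
        s = cfg.input_size
        base = np.full((1, s, s, 1), 0.1, dtype=np.float32)
        ref = net.forward(base, train=False)[0, s // 2, s // 2, 0]
        measured = np.zeros((s, s), dtype=bool)
        for i in range(s):
            for j in range(s):
                x = base.copy()
                x[0, i, j, 0] += 1.0
                out = net.forward(x, train=False)[0, s // 2, s // 2, 0]
                measured[i, j] = abs(out - ref) > 1e-7
        return measured

    def test_probe_matches_perturbation_oracle_on_real_network(self):
        cfg = NetConfig(input_size=16, depth_levels=3, base_channels=2,
                        convs_per_level=2, seed=0)
        np.testing.assert_array_equal(
            receptive_field_support(cfg), self._measured_support(cfg)
        )

    def test_probe_matches_oracle_with_three_convs_per_level(self):
        cfg = NetConfig(input_size=16, depth_levels=2, base_channels=2,
                        convs_per_level=3, seed=0)
        np.testing.assert_array_equal(
            receptive_field_support(cfg), self._measured_support(cfg)
        )

    def test_probe_size_must_match_depth(self):
        with pytest.raises(ValidationError, match="divisible"):
            receptive_field_support(NetConfig(input_size=512), probe_size=100)

    def test_more_depth_widens_field_of_view(self):
        shallow = NetConfig(input_size=64, depth_levels=2, base_channels=2)
        deep = NetConfig(input_size=64, depth_levels=4, base_channels=2)
        n_shallow = receptive_field_support(shallow).sum()
        n_deep = receptive_field_support(deep).sum()
        assert n_deep > n_shallow
        assert not covers_input(shallow)
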