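"""CNN machinery: losses, gradients, schedule, early stopping, determinism."""

import numpy as np
import pytest

from cephgrowth import nets


class TestL1Loss:
    def test_perfect_prediction_is_zero(self):
        loss, _ = nets.l1_loss(np.array([4.0, 9.0]), np.array([4.0, 9.0]))
        assert loss == 0.0

    def test_hand_computed_example(self):
        loss, _ = nets.l1_loss(np.array([5.0, 5.0]), np.array([4.0, 6.0]))
        assert loss == pytest.approx(1.0)

    def test_nonnegative_and_matches_bruteforce(self, rng):
        for _ in range(100):
            b = int(rng.integers(1, 20))
            pred = rng.normal(10, 5, b)
            true = rng.normal(10, 5, b)
            loss, _ = nets.l1_loss(pred, true)
            brute = sum(abs(t - p) for p, t in zip(pred, true)) / b
            assert loss >= 0
            assert loss == pytest.approx(brute, abs=1e-6)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            nets.l1_loss(np.array([]), np.array([]))


class TestSoftmaxXent:
    def test_equal_logits_give_ln2(self):
        loss, _ = nets.softmax_xent(np.array([[1.3, 1.3]]), np.array([1]))
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_male_logit_margin_example(self):
        # male logit 2, female 0, true male: p_male = 1/(1+e^-2)
        loss, _ = nets.softmax_xent(np.array([[2.0, 0.0]]), np.array([1]))
        assert loss == pytest.approx(-np.log(1 / (1 + np.exp(-2))), abs=1e-6)
        assert loss == pytest.approx(0.1269, abs=1e-4)

    def test_probabilities_normalized(self, rng):
        logits = rng.normal(0, 3, (50, 2))
        p = nets.softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            b = int(rng.integers(1, 16))
            logits = rng.normal(0, 2, (b, 2))
            g = rng.integers(0, 2, b)
            loss, _ = nets.softmax_xent(logits, g)
            brute = 0.0
            for n in range(b):
                pm = np.exp(logits[n, 0]) / np.exp(logits[n]).sum()
                pf = 1 - pm
                brute -= g[n] * np.log(pm) + (1 - g[n]) * np.log(pf)
            assert loss == pytest.approx(brute / b, abs=1e-9)

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            nets.softmax_xent(np.array([[np.inf, 0.0]]), np.array([1]))


class TestBuildModel:
    def test_age_head_single_output(self, rng):
        m = nets.build_model(nets.ModelConfig(input_side=32, channels=(4, 8)))
        out = m.forward(rng.random((3, 32, 32)).astype(np.float32),
                        train=False)
        assert out.shape == (3, 1)

    def test_sex_head_two_outputs(self, rng):
        m = nets.build_model(nets.ModelConfig(
            input_side=32, channels=(4, 8), head="sex_classification"))
        out = m.forward(rng.random((3, 32, 32)).astype(np.float32),
                        train=False)
        assert out.shape == (3, 2)

    def test_feature_stack_channels_and_stride(self, rng):
        m = nets.build_model(nets.ModelConfig(input_side=64,
                                              channels=(4, 8, 16)))
        feats = m.features(rng.random((2, 64, 64)).astype(np.float32))
        assert feats.shape == (2, 16, 8, 8)

    def test_efficientnet_backbone_unavailable(self):
        with pytest.raises(NotImplementedError, match="efficientnet_b0"):
            nets.build_model(nets.ModelConfig(backbone="efficientnet_b0"))

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            nets.build_model(nets.ModelConfig(backbone="resnet50"))

    def test_save_load_round_trip(self, rng, tmp_path):
        m = nets.build_model(nets.ModelConfig(input_side=32, channels=(4, 8)),
                             seed=3)
        x = rng.random((2, 32, 32)).astype(np.float32)
        m.save(tmp_path / "m.npz")
        m2 = nets.Model.load(tmp_path / "m.npz")
        assert np.allclose(m.forward(x, train=False),
                           m2.forward(x, train=False))


class TestBackpropagation:
    """Analytic gradients agree with central finite differences."""

    def _fd_check(self, model, param, grad, x, y, indices, tol=3e-3):
        eps = 1e-3
        bns = [l for l in model.layers if isinstance(l, nets.BatchNorm2d)]
        for idx in indices:
            stats = [(l.run_mean.copy(), l.run_var.copy()) for l in bns]
            orig = param[idx]
            param[idx] = orig + eps
            lp, _ = nets.l1_loss(model.forward(x, train=True)[:, 0], y)
            param[idx] = orig - eps
            lm, _ = nets.l1_loss(model.forward(x, train=True)[:, 0], y)
            param[idx] = orig
            for l, (rm, rv) in zip(bns, stats):
                l.run_mean[:], l.run_var[:] = rm, rv
            num = (lp - lm) / (2 * eps)
            assert abs(num - grad[idx]) < tol, f"{idx}: {num} vs {grad[idx]}"

    def test_conv_bn_linear_gradients(self, rng):
        cfg = nets.ModelConfig(input_side=16, channels=(3, 4))
        m = nets.Model(cfg, seed=1)
        x = rng.standard_normal((4, 16, 16)).astype(np.float32)
        y = rng.uniform(4, 19, 4).astype(np.float32)
        out = m.forward(x, train=True)
        _, g = nets.l1_loss(out[:, 0], y)
        m.backward(g[:, None])
        conv = m.feature_layers[0]
        self._fd_check(m, conv.W, conv.dW, x, y,
                       [(0, 0, 0, 0), (1, 0, 2, 1), (2, 0, 1, 1)])
        bn = m.feature_layers[1]
        self._fd_check(m, bn.gamma, bn.dgamma, x, y, [(0,), (2,)])
        lin = m.head_layers[-1]
        self._fd_check(m, lin.W, lin.dW, x, y, [(0, 0), (0, 3)])

    def test_squeeze_excite_gradients(self, rng):
        cfg = nets.ModelConfig(input_side=16, channels=(3, 4),
                               squeeze_excite=True)
        m = nets.Model(cfg, seed=2)
        x = rng.standard_normal((3, 16, 16)).astype(np.float32)
        y = rng.uniform(4, 19, 3).astype(np.float32)
        out = m.forward(x, train=True)
        _, g = nets.l1_loss(out[:, 0], y)
        m.backward(g[:, None])
        se = [l for l in m.feature_layers
              if isinstance(l, nets.SqueezeExcite)][0]
        self._fd_check(m, se.W1, se.dW1, x, y, [(0, 1)])
        self._fd_check(m, se.b2, se.db2, x, y, [(1,)])


@pytest.fixture(scope="module")
def toy_run():
    """A linearly-signaled toy set: brightness encodes age."""
    rng = np.random.default_rng(0)
    n, side = 120, 32
    ages = rng.uniform(4, 19, n).astype(np.float32)
    X = np.empty((n, side, side), np.float32)
    for i, a in enumerate(ages):
        X[i] = (a - 4) / 15 * 0.8 + rng.normal(0, 0.02, (side, side))
    m = nets.build_model(nets.ModelConfig(input_side=side,
                                          channels=(4, 8)), seed=0)
    cfg = nets.TrainConfig(seed=0, max_epochs=12, min_updates=10,
                           augment=None)
    model, hist = nets.train(m, X[:90], ages[:90], X[90:], ages[90:], cfg)
    return model, hist, X, ages, cfg


class TestTrainingProtocol:
    def test_lr_schedule_arithmetic(self):
        cfg = nets.TrainConfig(lr0=1e-3)
        assert cfg.lr_at(1) == pytest.approx(1e-3)
        assert cfg.lr_at(5) == pytest.approx(1e-3)
        assert cfg.lr_at(6) == pytest.approx(8e-4)
        assert cfg.lr_at(11) == pytest.approx(6.4e-4)

    def test_training_reduces_loss(self, toy_run):
        _, hist, *_ = toy_run
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_returned_model_attains_best_val_loss(self, toy_run):
        model, hist, X, ages, _ = toy_run
        val = nets.evaluate_loss(model, X[90:], ages[90:])
        assert val == pytest.approx(min(h["val_loss"] for h in hist),
                                    rel=1e-5)

    def test_history_is_deterministic(self, toy_run):
        model, hist, X, ages, cfg = toy_run
        m2 = nets.build_model(nets.ModelConfig(input_side=32,
                                               channels=(4, 8)), seed=0)
        _, hist2 = nets.train(m2, X[:90], ages[:90], X[90:], ages[90:], cfg)
        assert [h["train_loss"] for h in hist] == \
               [h["train_loss"] for h in hist2]

    def test_patience_stops_training(self):
        # constant labels with pure-noise inputs: validation cannot improve
        rng = np.random.default_rng(1)
        X = rng.random((64, 16, 16)).astype(np.float32)
        y = np.full(64, 10.0, np.float32)
        m = nets.build_model(nets.ModelConfig(input_side=16, channels=(2,)),
                             seed=0)
        cfg = nets.TrainConfig(seed=0, max_epochs=50, min_updates=1,
                               patience=3, augment=None, lr0=0.0)
        _, hist = nets.train(m, X[:48], y[:48], X[48:], y[48:], cfg)
        assert len(hist) < 50

    def test_empty_split_rejected(self):
        m = nets.build_model(nets.ModelConfig(input_side=16, channels=(2,)))
        with pytest.raises(ValueError):
            nets.train(m, np.empty((0, 16, 16)), np.empty(0),
                       np.ones((2, 16, 16)), np.ones(2))


class TestPredict:
    def test_eval_mode_deterministic(self, rng):
        m = nets.build_model(nets.ModelConfig(input_side=32, channels=(4, 8)))
        x = rng.random((4, 32, 32)).astype(np.float32)
        assert np.array_equal(nets.predict(m, x), nets.predict(m, x))

    def test_sex_probabilities_valid(self, rng):
        m = nets.build_model(nets.ModelConfig(
            input_side=32, channels=(4, 8), head="sex_classification"))
        p = nets.predict(m, rng.random((6, 32, 32)).astype(np.float32))
        assert p.shape == (6, 2)
        assert (p >= 0).all() and (p <= 1).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
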