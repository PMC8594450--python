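"""CNN engine and trainable models: gradients, architecture contracts,
training behaviour, and warm starts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from iqtask._rng import stream_rng
from iqtask.imaging import ImagingEnsemble, build_task_ensembles
from iqtask.nn import (
    ObserverNetworkSpec,
    ResNetObserver,
    SRCNN,
    SRNetworkSpec,
    TrainingConfig,
    apply_sr,
    expected_srcnn_parameters,
    train_observer,
    train_sr,
)
from iqtask.nn._engine import bce_with_logits, mse_loss
from iqtask.phantoms import CLBParams


class TestArchitecture:
    def test_default_parameter_count(self):
        """3 layers, channels 1->32->32->1, kernels (9,5,5):
        (81*32+32) + (25*1024+32) + (25*32+1) parameters."""
        spec = SRNetworkSpec(n_layers=3)
        expected = 81 * 32 + 32 + 25 * 32 * 32 + 32 + 25 * 32 + 1
        assert expected_srcnn_parameters(spec) == expected == 29_057
        model = SRCNN(spec, np.random.default_rng(0))
        assert model.n_parameters() == expected

    @pytest.mark.parametrize("n_layers", range(2, 9))
    def test_depth_grid_builds_and_preserves_shape(self, n_layers):
        model = SRCNN(SRNetworkSpec(n_layers=n_layers, hidden_channels=4), np.random.default_rng(1))
        x = np.random.default_rng(2).standard_normal((2, 1, 16, 16)).astype(np.float32)
        assert model.forward(x).shape == (2, 1, 16, 16)

    def test_too_shallow_rejected(self):
        with pytest.raises(ValueError):
            SRNetworkSpec(n_layers=1)

    @pytest.mark.parametrize("n_blocks", [2, 4, 6, 8])
    def test_observer_blocks_build_scalar_output(self, n_blocks):
        spec = ObserverNetworkSpec(n_blocks=n_blocks, input_size=12, channels=4)
        model = ResNetObserver(spec, np.random.default_rng(3))
        x = np.random.default_rng(4).standard_normal((3, 1, 12, 12)).astype(np.float32)
        assert model.forward(x).shape == (3,)

    def test_warm_start_size_checked(self):
        spec = ObserverNetworkSpec(n_blocks=2, input_size=8, channels=4)
        with pytest.raises(ValueError, match="template"):
            ResNetObserver(spec, np.random.default_rng(5), warm_start=np.zeros(10))


class TestGradients:
    def test_srcnn_gradients_match_finite_differences(self):
        rng = np.random.default_rng(6)
        model = SRCNN(SRNetworkSpec(2, 3, 3, 2), rng)
        model.net.layers[-1].w[...] = rng.standard_normal(model.net.layers[-1].w.shape) * 0.3
        x = rng.standard_normal((2, 1, 6, 6)).astype(np.float32)
        y = rng.standard_normal((2, 1, 6, 6)).astype(np.float32)
        loss, grad = mse_loss(model.forward(x), y)
        model.backward(grad.astype(np.float32))
        analytic = [g.copy() for g in model.grads()]
        eps = 1e-3
        for p_idx, (i,) in [(0, (5,)), (1, (1,))]:
            p = model.params()[p_idx].ravel()
            g = analytic[p_idx].ravel()
            old = p[i]
            p[i] = old + eps
            lp, _ = mse_loss(model.forward(x), y)
            p[i] = old - eps
            lm, _ = mse_loss(model.forward(x), y)
            p[i] = old
            assert g[i] == pytest.approx((lp - lm) / (2 * eps), abs=2e-4)

    def test_observer_gain_gradient(self):
        rng = np.random.default_rng(7)
        spec = ObserverNetworkSpec(n_blocks=1, input_size=8, channels=3)
        model = ResNetObserver(spec, rng, warm_start=rng.standard_normal(64))
        x = rng.standard_normal((4, 1, 8, 8)).astype(np.float32)
        lab = np.array([0, 1, 0, 1])
        loss, grad = bce_with_logits(model.forward(x), lab)
        model.backward(grad.astype(np.float32), x.shape)
        g_analytic = model.grads()[-1][0]
        eps = 1e-3
        old = model.gain[0]
        model.gain[0] = old + eps
        lp, _ = bce_with_logits(model.forward(x), lab)
        model.gain[0] = old - eps
        lm, _ = bce_with_logits(model.forward(x), lab)
        model.gain[0] = old
        assert g_analytic == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)

    def test_bce_stable_for_large_logits(self):
        loss, grad = bce_with_logits(np.array([500.0, -500.0]), np.array([1.0, 0.0]))
        assert np.isfinite(loss) and loss < 1e-6
        assert np.all(np.isfinite(grad))


class TestSRTraining:
    @pytest.fixture(scope="class")
    def toy_pairs(self):
        rng = np.random.default_rng(8)
        from iqtask.imaging import gaussian_blur

        hr = np.stack([
            gaussian_blur(rng.standard_normal((16, 16)), 1.0) for _ in range(64)
        ]).astype(np.float32)
        return hr

    def test_identity_task_converges(self, toy_pairs):
        """Training LR==HR drives the loss well below its starting value."""
        hr = toy_pairs
        model = SRCNN(SRNetworkSpec(2, 5, 3, 4), np.random.default_rng(9))
        cfg = TrainingConfig(batch_size=8, learning_rate=3e-3, max_epochs=30, seed=1, residual=False)
        hist = train_sr(model, hr, hr, cfg)
        assert hist["train_loss"][-1] < 0.1 * hist["train_loss"][0]
        out = model.predict(hr)
        assert np.mean((out - hr) ** 2) < 0.1 * np.var(hr)

    def test_training_deterministic(self, toy_pairs):
        hr = toy_pairs
        histories = []
        for _ in range(2):
            model = SRCNN(SRNetworkSpec(2, 5, 3, 4), np.random.default_rng(10))
            cfg = TrainingConfig(batch_size=8, learning_rate=1e-3, max_epochs=3, seed=2)
            histories.append(train_sr(model, hr, hr + 0.1, cfg)["train_loss"])
        assert histories[0] == histories[1]

    def test_validation_checkpoint_selected(self, toy_pairs):
        hr = toy_pairs
        model = SRCNN(SRNetworkSpec(2, 5, 3, 4), np.random.default_rng(11))
        cfg = TrainingConfig(batch_size=8, learning_rate=3e-3, max_epochs=10, seed=3)
        hist = train_sr(model, hr[:48], hr[:48] + 0.05, cfg, hr[48:], hr[48:] + 0.05)
        assert min(hist["val_loss"]) <= hist["val_loss"][-1]

    def test_shape_mismatch_rejected(self, toy_pairs):
        model = SRCNN(SRNetworkSpec(2, 5, 3, 4), np.random.default_rng(12))
        with pytest.raises(ValueError):
            train_sr(model, toy_pairs, toy_pairs[:, :8, :8], TrainingConfig())

    def test_apply_sr_contract(self, toy_pairs):
        hr = toy_pairs
        labels = np.tile([0, 1], 32).astype(np.int8)
        ens = ImagingEnsemble(hr, labels, "LR")
        model = SRCNN(SRNetworkSpec(2, 5, 3, 4), np.random.default_rng(13))
        out1 = apply_sr(model, ens)
        out2 = apply_sr(model, ens)
        assert out1.resolution_class == "SR"
        assert len(out1) == len(ens)
        np.testing.assert_array_equal(out1.labels, ens.labels)
        np.testing.assert_array_equal(out1.images, out2.images)  # deterministic
        assert "warning" in out1.generation_spec  # untrained model flagged


class TestObserverTraining:
    @pytest.fixture(scope="class")
    def separable_sets(self):
        rng = np.random.default_rng(14)
        n = 60
        x0 = rng.standard_normal((n, 12, 12)).astype(np.float32)
        x1 = rng.standard_normal((n, 12, 12)).astype(np.float32) + 2.0
        imgs = np.concatenate([x0, x1])
        labels = np.repeat(np.array([0, 1], dtype=np.int8), n)
        perm = rng.permutation(2 * n)
        train = ImagingEnsemble(imgs[perm][: 2 * n - 40], labels[perm][: 2 * n - 40], "HR")
        val = ImagingEnsemble(imgs[perm][2 * n - 40 :], labels[perm][2 * n - 40 :], "HR")
        return train, val

    def test_separable_classes_reach_perfect_auc(self, separable_sets):
        train, val = separable_sets
        spec = ObserverNetworkSpec(n_blocks=2, input_size=12, channels=4)
        model = ResNetObserver(spec, np.random.default_rng(15))
        hist = train_observer(model, train, val, TrainingConfig(
            batch_size=16, learning_rate=3e-3, max_epochs=15, seed=4))
        assert max(hist["val_auc"]) > 0.99

    def test_single_class_rejected(self, separable_sets):
        train, val = separable_sets
        bad = train.subset(train.labels == 0)
        spec = ObserverNetworkSpec(n_blocks=1, input_size=12, channels=4)
        model = ResNetObserver(spec, np.random.default_rng(16))
        with pytest.raises(ValueError):
            train_observer(model, bad, val, TrainingConfig())

    def test_warm_start_reproduces_rho_ranking(self):
        """Before training, a warm-started observer ranks images like the
        RHO template it was initialized from."""
        from iqtask.observers import central_crop, fit_covariance_model, rho_template

        clb = CLBParams(field_size=32, mean_clusters=40)
        hr, _ = build_task_ensembles(
            "rayleigh", 60, stream_rng(17, "clb"), clb=clb, signal_lengths=7
        )
        f0 = hr.images[hr.labels == 0]
        f1 = hr.images[hr.labels == 1]
        tpl = rho_template(fit_covariance_model(f0, f1, crop=16), 1e-6)
        spec = ObserverNetworkSpec(n_blocks=2, input_size=16, channels=4)
        model = ResNetObserver(spec, np.random.default_rng(18), warm_start=tpl.weights)
        crops = central_crop(hr.images, 16)
        net_scores = model.score(crops)
        rho_scores = crops.reshape(len(crops), -1) @ tpl.weights
        rho_corr = spearmanr(net_scores, rho_scores).statistic
        assert rho_corr > 0.9

    def test_flip_augmentation_quadruples_data(self):
        from iqtask.nn.train import _flip_augment

        rng = np.random.default_rng(19)
        imgs = rng.random((6, 8, 8))
        labels = np.array([0, 1] * 3, dtype=np.int8)
        aug, lab = _flip_augment(imgs, labels)
        assert len(aug) == 24 and len(lab) == 24
        np.testing.assert_array_equal(lab[:6], labels)
        np.testing.assert_array_equal(aug[6], imgs[0][::-1])

    def test_semionline_noise_redraws_each_epoch(self):
        """With semionline learning the training inputs change every epoch
        while labels and the clean objects stay fixed."""
        clb = CLBParams(field_size=32, mean_clusters=40)
        hr, _ = build_task_ensembles(
            "rayleigh", 20, stream_rng(20, "clb"), clb=clb, signal_lengths=7, keep_clean=True
        )
        from iqtask.imaging import redraw_noise

        rng = np.random.default_rng(21)
        epoch1 = redraw_noise(hr, rng)
        epoch2 = redraw_noise(hr, rng)
        assert not np.array_equal(epoch1, epoch2)
        # training with semionline noise runs and still learns
        val, _ = build_task_ensembles(
            "rayleigh", 10, stream_rng(22, "clb"), clb=clb, signal_lengths=7
        )
        spec = ObserverNetworkSpec(n_blocks=1, input_size=16, channels=4)
        model = ResNetObserver(spec, np.random.default_rng(23))
        hist = train_observer(model, hr, val, TrainingConfig(
            batch_size=8, learning_rate=1e-3, max_epochs=3, seed=5, semionline_noise=True),
            crop=16)
        assert len(hist["val_auc"]) == 3

    def test_observer_training_deterministic(self, separable_sets):
        train, val = separable_sets
        scores = []
        for _ in range(2):
            spec = ObserverNetworkSpec(n_blocks=1, input_size=12, channels=4)
            model = ResNetObserver(spec, np.random.default_rng(24))
            train_observer(model, train, val, TrainingConfig(
                batch_size=16, learning_rate=1e-3, max_epochs=2, seed=6))
            scores.append(model.score(val.images))
        np.testing.assert_array_equal(scores[0], scores[1])
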