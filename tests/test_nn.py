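"""Neural engine: layer gradients, encoders, heads, focal loss,
augmentation and the training loop contract."""

import numpy as np
import pytest

import lesiontrack as lt
from lesiontrack.config import EncoderConfig, TrainConfig, scaled
from lesiontrack.models import CohortData, ConvGRUModel, SimpleCNNModel
from lesiontrack import nn


def _num_grad(f, x, eps=1e-3):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


class TestLayerGradients:
    """Backprop of each layer agrees with finite differences."""

    def _check(self, layer, x, train=True, tol=2e-2):
        rng = np.random.default_rng(0)
        out = layer.forward(x.copy(), train=train)
        w = rng.normal(size=out.shape).astype(np.float32)

        def loss():
            return float((layer.forward(x.copy(), train=train) * w).sum())

        for p in layer.params():
            p.grad[...] = 0.0
        layer.forward(x.copy(), train=train)
        dx = layer.backward(w)
        ng = _num_grad(loss, x)
        np.testing.assert_allclose(dx, ng, atol=tol, rtol=tol)
        for p in layer.params():
            analytic = p.grad.copy()
            numeric = _num_grad(loss, p.value)
            np.testing.assert_allclose(analytic, numeric, atol=tol, rtol=tol)

    def test_conv2d(self, rng):
        layer = nn.Conv(2, 3, 3, stride=2, pad=1, ndim=2, rng=rng)
        self._check(layer, rng.normal(size=(2, 2, 6, 6)).astype(np.float32))

    def test_conv3d(self, rng):
        layer = nn.Conv(1, 2, 3, stride=1, pad=1, ndim=3, rng=rng)
        self._check(layer, rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32))

    def test_batchnorm_train_mode(self, rng):
        layer = nn.BatchNorm(3, ndim=2)
        layer.gamma.value[:] = rng.uniform(0.5, 1.5, 3).astype(np.float32)
        self._check(layer, rng.normal(size=(3, 3, 4, 4)).astype(np.float32))

    def test_linear(self, rng):
        layer = nn.Linear(5, 3, rng=rng)
        self._check(layer, rng.normal(size=(4, 5)).astype(np.float32))

    def test_maxpool(self, rng):
        layer = nn.MaxPool(2, 2, 0, ndim=2)
        # distinct values so the argmax is stable under the fd perturbation
        x = (np.arange(2 * 2 * 4 * 4).reshape(2, 2, 4, 4).astype(np.float32)
             + rng.normal(0, 0.01, (2, 2, 4, 4)).astype(np.float32))
        self._check(layer, x)

    def test_basic_block(self, rng):
        layer = nn.BasicBlock(2, 4, stride=2, ndim=2, rng=rng)
        self._check(layer, rng.normal(size=(2, 2, 6, 6)).astype(np.float32), tol=5e-2)

    def test_gru_cell(self, rng):
        cell = nn.GRUCell(4, 3, rng=rng)
        x = rng.normal(size=(2, 3, 4)).astype(np.float32)
        w = rng.normal(size=(2, 3)).astype(np.float32)

        def loss():
            return float((cell.forward(x.copy()) * w).sum())

        cell.forward(x.copy())
        dx = cell.backward(w)
        np.testing.assert_allclose(dx, _num_grad(loss, x), atol=2e-2, rtol=2e-2)
        for p in cell.params():
            p.grad[...] = 0.0
        cell.forward(x.copy())
        cell.backward(w)
        for p in cell.params():
            analytic = p.grad.copy()
            np.testing.assert_allclose(
                analytic, _num_grad(loss, p.value), atol=2e-2, rtol=2e-2
            )


class TestEncoder:
    def test_full_scale_feature_length(self):
        cfg = EncoderConfig(dims="2d", width=1.0, feature_dim=512,
                            blocks=(3, 4, 6, 3), input_shape=(96, 96))
        enc = nn.ResNetEncoder(cfg, rng=np.random.default_rng(0))
        out = enc.forward(np.zeros((1, 3, 96, 96), dtype=np.float32))
        assert out.shape == (1, 512)

    def test_desk_width_and_feature_dim_plumbing(self, desk):
        enc = nn.ResNetEncoder(desk.encoder_2d, rng=np.random.default_rng(0))
        out = enc.forward(np.zeros((2, 3, 48, 48), dtype=np.float32))
        assert out.shape == (2, 64)

    def test_eval_mode_deterministic(self, desk, rng):
        enc = nn.ResNetEncoder(desk.encoder_2d, rng=np.random.default_rng(1))
        x = rng.normal(size=(1, 3, 48, 48)).astype(np.float32)
        a = enc.forward(x.copy())
        b = enc.forward(x.copy())
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_names_expectation(self, desk):
        enc = nn.ResNetEncoder(desk.encoder_2d)
        with pytest.raises(ValueError, match=r"\(N, 3, 48, 48\)"):
            enc.forward(np.zeros((1, 3, 96, 96), dtype=np.float32))

    def test_3d_encoder_forward(self, desk):
        enc = nn.ResNetEncoder(desk.encoder_3d, rng=np.random.default_rng(0))
        out = enc.forward(np.zeros((1, 1, 32, 48, 48), dtype=np.float32))
        assert out.shape == (1, 64)


class TestHeads:
    def test_concat_head_input_dim_2048(self):
        head = nn.ConcatHead(4, 512)
        assert head.input_dim == 2048
        logits = head.forward(np.zeros((2, 4, 512), dtype=np.float32))
        assert logits.shape == (2,)

    def test_concat_head_wrong_count_rejected(self):
        head = nn.ConcatHead(4, 8)
        with pytest.raises(ValueError, match="exactly 4"):
            head.forward(np.zeros((1, 3, 8), dtype=np.float32))

    def test_zero_input_logit_is_bias(self):
        head = nn.ConcatHead(4, 8)
        head.fc.b.value[:] = 0.37
        logits = head.forward(np.zeros((3, 4, 8), dtype=np.float32))
        np.testing.assert_allclose(logits, 0.37, atol=1e-6)

    def test_gru_accepts_length_one(self):
        head = nn.GRUHead(8, rng=np.random.default_rng(0))
        out = head.forward(np.zeros((2, 1, 8), dtype=np.float32))
        assert out.shape == (2,) and np.isfinite(out).all()

    def test_gru_order_sensitivity(self, rng):
        head = nn.GRUHead(8, rng=np.random.default_rng(3))
        x = rng.normal(size=(1, 4, 8)).astype(np.float32)
        a = head.forward(x)
        b = head.forward(x[:, ::-1].copy())
        assert abs(float(a[0]) - float(b[0])) > 1e-6

    def test_zero_initialised_gru_logit_is_output_bias(self):
        head = nn.GRUHead(8, rng=np.random.default_rng(0))
        for p in head.cell.params():
            p.value[...] = 0.0
        head.out.W.value[...] = 0.0
        head.out.b.value[:] = -1.25
        out = head.forward(np.zeros((2, 4, 8), dtype=np.float32))
        np.testing.assert_allclose(out, -1.25, atol=1e-7)


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy_value(self):
        assert nn.focal_loss([0.5], gamma=0.0, alpha=1.0) == pytest.approx(np.log(2))

    def test_confident_correct_prediction_vanishes(self):
        assert nn.focal_loss([1.0 - 1e-9], gamma=2.0) == pytest.approx(0.0, abs=1e-6)

    def test_gamma_two_analytic_value(self):
        # 0.01 * (-ln 0.9)
        assert nn.focal_loss([0.9], gamma=2.0) == pytest.approx(1.0536e-3, rel=1e-3)

    def test_gamma_zero_equals_bce(self, rng):
        """With gamma=0 and unit weight the focal loss is cross-entropy."""
        logits = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        p = 1 / (1 + np.exp(-logits))
        p_true = np.where(y == 1, p, 1 - p)
        bce = -np.mean(np.log(p_true))
        assert nn.focal_loss(p_true, gamma=0.0, alpha=1.0) == pytest.approx(bce, abs=1e-12)
        # the class-weighted logits form at alpha=0.5 is half the BCE
        loss, _ = nn.focal_loss_with_logits(logits, y, gamma=0.0, alpha_pos=0.5)
        assert loss == pytest.approx(bce / 2, abs=1e-12)

    @pytest.mark.parametrize("gamma,alpha", [(0.0, 1.0), (2.0, 0.75), (0.5, 0.5)])
    def test_gradient_matches_finite_differences(self, gamma, alpha, rng):
        logits = rng.normal(size=20)
        y = rng.integers(0, 2, 20)
        _, g = nn.focal_loss_with_logits(logits, y, gamma, alpha)

        def f(s):
            return nn.focal_loss_with_logits(s, y, gamma, alpha)[0]

        num = np.zeros_like(logits)
        eps = 1e-5
        for i in range(len(logits)):
            up = logits.copy(); up[i] += eps
            dn = logits.copy(); dn[i] -= eps
            num[i] = (f(up) - f(dn)) / (2 * eps)
        np.testing.assert_allclose(g, num, atol=1e-6)


class TestAugmentation:
    def test_identity_parameters_are_noop(self, rng):
        img = rng.uniform(-1, 1, size=(3, 24, 24)).astype(np.float32)
        out = nn.apply_augment(img, nn.AugmentParams.identity(2))
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_flip_is_involution(self, rng):
        img = rng.uniform(-1, 1, size=(3, 24, 24)).astype(np.float32)
        p = nn.AugmentParams(0.0, 1.0, True, (0.0, 0.0))
        twice = nn.apply_augment(nn.apply_augment(img, p), p)
        np.testing.assert_allclose(twice, img, atol=1e-5)

    def test_translation_moves_a_spike(self):
        img = np.full((1, 21, 21), -1.0, dtype=np.float32)
        img[0, 10, 10] = 1.0
        p = nn.AugmentParams(0.0, 1.0, False, (0.0, 5.0))
        out = nn.apply_augment(img, p)
        assert out[0, 10, 15] == pytest.approx(1.0)

    def test_3d_translation_moves_a_spike(self):
        img = np.full((1, 11, 11, 11), -1.0, dtype=np.float32)
        img[0, 5, 5, 5] = 1.0
        p = nn.AugmentParams(0.0, 1.0, False, (2.0, 0.0, -3.0))
        out = nn.apply_augment(img, p)
        assert out[0, 7, 5, 2] == pytest.approx(1.0)

    def test_output_clipped_to_valid_range(self, rng):
        img = rng.uniform(-1, 1, size=(3, 24, 24)).astype(np.float32)
        cfg = TrainConfig()
        for _ in range(5):
            p = nn.sample_augment(rng, cfg, 2)
            out = nn.apply_augment(img, p)
            assert out.min() >= -1.0 and out.max() <= 1.0

    def test_mask_diameter_scales_with_augmentation(self):
        """In-plane lesion extent follows the scale factor within 2 px."""
        from lesiontrack.features import measure_dmax

        mask = np.zeros((1, 48, 48), dtype=np.uint8)
        yy, xx = np.indices((48, 48))
        mask[0] = ((yy - 24) ** 2 + (xx - 24) ** 2 <= 10**2)
        img = mask.astype(np.float32)
        d0 = measure_dmax(mask, (1.0, 1.0, 1.0))
        for scale in (0.85, 1.0, 1.15):
            p = nn.AugmentParams(17.0, scale, False, (0.0, 0.0))
            _, m2 = nn.apply_augment(img, p, mask=mask)
            d = measure_dmax(m2, (1.0, 1.0, 1.0))
            assert abs(d - scale * d0) <= 2.0


class TestTraining:
    def test_lr_schedule_as_printed(self):
        cfg = TrainConfig()
        assert cfg.lr_at_epoch(1) == 1e-4
        assert cfg.lr_at_epoch(12) == 1e-5
        assert cfg.lr_at_epoch(18) == 1e-6

    def test_history_records_schedule(self, tiny_cohort):
        cfg = scaled(tiny_cohort.profile, epochs=1).train
        res = ConvGRUModel(tiny_cohort, dims="2d", train_config=cfg).fit(seed=0)
        assert list(res.history["lr"]) == [1e-4]
        assert res.history.shape[0] == 1

    def test_same_seed_same_first_epoch_loss(self, tiny_cohort, micro_train_config):
        a = ConvGRUModel(tiny_cohort, dims="2d", train_config=micro_train_config).fit(seed=4)
        b = ConvGRUModel(tiny_cohort, dims="2d", train_config=micro_train_config).fit(seed=4)
        assert a.history["loss"][0] == b.history["loss"][0]

    def test_overfit_smoke_loss_decreases(self, tiny_cohort):
        """Training loss falls over 10 epochs on a small cohort."""
        sub = CohortData(tiny_cohort.cases[:10], tiny_cohort.profile)
        if len(np.unique(sub.labels)) < 2:
            sub = CohortData(tiny_cohort.cases[:14], tiny_cohort.profile)
        cfg = scaled(tiny_cohort.profile, epochs=10, augment=False).train
        res = ConvGRUModel(sub, dims="2d", train_config=cfg).fit(seed=0)
        assert res.history["loss"].iloc[-1] < res.history["loss"].iloc[0]

    def test_single_class_cohort_rejected(self, tiny_cohort, micro_train_config):
        sub = CohortData(
            [c for c in tiny_cohort.cases if c.y == 0], tiny_cohort.profile
        )
        with pytest.raises(ValueError, match="single class"):
            ConvGRUModel(sub, dims="2d", train_config=micro_train_config).fit()

    def test_gru_scores_finite_for_shorter_sequences(self, tiny_cohort, micro_train_config):
        """A GRU head trained on 4 timepoints scores 1-3 timepoint inputs."""
        res = ConvGRUModel(tiny_cohort, dims="2d", train_config=micro_train_config).fit(seed=0)
        for k in (1, 2, 3):
            s = res.predict(tiny_cohort, n_timepoints=k)
            assert np.isfinite(s).all() and (0 <= s).all() and (s <= 1).all()

    def test_simple_cnn_3d_smoke(self, tiny_cohort, micro_train_config):
        sub = CohortData(tiny_cohort.cases[:12], tiny_cohort.profile)
        if len(np.unique(sub.labels)) < 2:
            sub = CohortData(tiny_cohort.cases[:16], tiny_cohort.profile)
        res = SimpleCNNModel(sub, dims="3d", train_config=micro_train_config).fit(seed=0)
        s = res.predict(sub)
        assert np.isfinite(s).all()


class TestGammaGrid:
    def test_single_value_grid(self):
        got = lt.tune_focal_gamma(lambda g: [0.1, 0.9], np.array([0, 1]), gamma_grid=(3.0,))
        assert got == 3.0

    def test_better_gamma_wins(self):
        labels = np.array([0, 0, 1, 1])

        def fit_and_score(gamma):
            return [0.1, 0.2, 0.8, 0.9] if gamma == 1.0 else [0.8, 0.2, 0.1, 0.9]

        assert lt.tune_focal_gamma(fit_and_score, labels, gamma_grid=(0.0, 1.0)) == 1.0

    def test_tie_takes_smaller_gamma(self):
        labels = np.array([0, 1])
        assert lt.tune_focal_gamma(lambda g: [0.1, 0.9], labels, gamma_grid=(2.0, 5.0)) == 2.0

    def test_degenerate_validation_falls_back(self):
        with pytest.warns(UserWarning, match="single-class"):
            got = lt.tune_focal_gamma(lambda g: [0.5], np.array([1]), gamma_grid=(0.0, 1.0))
        assert got == 2.0
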