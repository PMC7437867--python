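"""Network geometry, training mechanics, lesions, decoders, head retraining."""


import numpy as np
import pytest

from liquidperc import _nn
from liquidperc import slowfusion as sf


@pytest.fixture(scope="module")
def tiny_net(tiny_cfg):
    return sf.build_network(tiny_cfg, seed=7)


@pytest.fixture(scope="module")
def random_clips():
    return np.random.default_rng(0).random((12, 20, 64, 64, 3)).astype(np.float32)


class TestGeometry:
    def test_default_conv_unit_registry(self):
        net = sf.build_network(sf.SlowFusionConfig(), seed=0)
        assert net.registry.n_conv == 420
        assert net.registry.layer_sizes["relu1"] == 256
        assert net.registry.layer_sizes["relu2"] == 64
        assert net.registry.layer_sizes["relu3"] == 100

    def test_stage1_pathway_count(self):
        cfg = sf.SlowFusionConfig()
        assert cfg.n_pathways1 == (20 - 8) // 4 + 1 == 4
        assert cfg.n_pathways2 == 3

    @pytest.mark.parametrize("stage,frames", [(1, 8), (2, 12), (3, 20), (4, 20)])
    def test_temporal_receptive_fields(self, stage, frames):
        assert sf.temporal_receptive_field(sf.SlowFusionConfig(), stage) == frames

    def test_unknown_stage(self):
        with pytest.raises(ValueError):
            sf.temporal_receptive_field(sf.SlowFusionConfig(), 5)

    def test_inconsistent_temporal_geometry(self):
        with pytest.raises(ValueError):
            sf.SlowFusionConfig(t_extent1=7).validate()

    def test_same_seed_identical_weights(self, tiny_cfg):
        a = sf.build_network(tiny_cfg, seed=3)
        b = sf.build_network(tiny_cfg, seed=3)
        for la, lb in zip(a.layers(), b.layers()):
            assert np.array_equal(la.W, lb.W)

    def test_pathway_windows_tile_clip(self):
        cfg = sf.SlowFusionConfig()
        covered = set()
        for i in range(cfg.n_pathways1):
            covered |= set(range(i * cfg.t_stride, i * cfg.t_stride + cfg.t_extent1))
        assert covered == set(range(20))


class TestForwardBackward:
    def test_gradient_matches_numeric(self, tiny_net, random_clips):
        x = random_clips[:1]
        gx = tiny_net.backward(np.ones(1, dtype=np.float32),
                               tiny_net.forward(x)[2], need_input_grad=True)
        i = np.unravel_index(np.abs(gx).argmax(), gx.shape)
        eps = 1e-3
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        num = (tiny_net.forward(xp)[0][0] - tiny_net.forward(xm)[0][0]) / (2 * eps)
        assert gx[i] == pytest.approx(num, rel=0.02, abs=1e-4)

    def test_predict_deterministic_and_duplicate_consistent(self, tiny_net, random_clips):
        batch = np.concatenate([random_clips[:3], random_clips[2:3]])
        p = sf.predict(tiny_net, batch)
        q = sf.predict(tiny_net, batch)
        assert np.array_equal(p, q)
        assert p[2] == p[3]

    def test_bad_shape_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="shape"):
            tiny_net.forward(np.zeros((1, 10, 64, 64, 3), dtype=np.float32))

    def test_unknown_transform_rejected(self, tiny_net, random_clips):
        with pytest.raises(ValueError):
            sf.predict(tiny_net, random_clips[:1], "sepia")

    def test_grayscale_idempotent(self, tiny_net, random_clips):
        g = sf.grayscale(random_clips[:4])
        assert np.allclose(sf.predict(tiny_net, g, "grayscale"),
                           sf.predict(tiny_net, g), atol=1e-5)


class TestColourAblation:
    def test_grayscale_does_not_beat_colour(self, trained_session):
        """Palettes are viscosity-uninformative, so removing colour cannot
        systematically improve prediction."""
        s = trained_session
        val = s["val_idx"][:160]
        clips, labels = s["clips"][val], s["labels"][val]
        rmse_colour = float(np.sqrt(np.mean(
            (sf.predict(s["net"], clips) - labels) ** 2)))
        rmse_gray = float(np.sqrt(np.mean(
            (sf.predict(s["net"], clips, "grayscale") - labels) ** 2)))
        assert rmse_gray >= rmse_colour - 0.25


class TestTraining:
    def test_zero_lr_zero_l2_leaves_weights(self, tiny_cfg, random_clips):
        net = sf.build_network(tiny_cfg, seed=1)
        before = [l.W.copy() for l in net.layers()]
        y = np.linspace(1, 16, len(random_clips)).astype(np.float32)
        sf.train(net, random_clips, y, epochs=2, seed=0, lr=0.0)
        for w0, layer in zip(before, net.layers()):
            assert np.array_equal(w0, layer.W)

    def test_toy_set_fitting(self, tiny_cfg, random_clips):
        """Training reduces RMSE well below the untrained model's."""
        net = sf.build_network(tiny_cfg, seed=1)
        y = np.linspace(1, 16, 10).astype(np.float32)
        base = float(np.sqrt(np.mean((net.predict(random_clips[:10]) - y) ** 2)))
        hist = sf.train(net, random_clips[:10], y, epochs=200, seed=0, lr=5e-3)
        fitted = float(np.sqrt(np.mean((net.predict(random_clips[:10]) - y) ** 2)))
        assert fitted < base
        assert fitted < 2.0
        assert len(hist) == 200

    def test_history_length_and_label_checks(self, tiny_cfg, random_clips):
        net = sf.build_network(tiny_cfg, seed=1)
        y = np.full(len(random_clips), 5.0, dtype=np.float32)
        h = sf.train(net, random_clips, y, random_clips[:2], y[:2], y[:2],
                     epochs=3, seed=0, lr=1e-3)
        assert len(h.train_physical) == len(h.val_physical) == 3
        with pytest.raises(ValueError, match="empty"):
            sf.train(net, random_clips[:0], y[:0])
        with pytest.raises(ValueError, match="1..16"):
            sf.train(net, random_clips[:2], np.array([0.0, 5.0]))


class TestActivationsAndLesions:
    def test_unit_counts_match_registry(self, tiny_net, random_clips):
        for layer in sf.RELU_LAYERS:
            rec = sf.collect_activations(tiny_net, random_clips[:4], layer)
            assert rec.n_units == tiny_net.registry.layer_sizes[layer]
            assert np.all(rec.responses >= 0)

    def test_zero_input_zero_relu(self, tiny_cfg):
        net = sf.build_network(tiny_cfg, seed=2)
        for layer in net.conv1 + net.conv2 + net.conv3 + [net.fc4]:
            layer.b[:] = 0.0
        x = np.zeros((2, 20, 64, 64, 3), dtype=np.float32)
        for layer in sf.RELU_LAYERS:
            rec = sf.collect_activations(net, x, layer)
            assert np.all(rec.responses == 0)
            assert len(rec.dead_units()) == rec.n_units

    def test_empty_lesion_is_noop(self, tiny_net, random_clips):
        lesioned = sf.lesion_units(tiny_net, [])
        assert np.array_equal(lesioned.predict(random_clips),
                              tiny_net.predict(random_clips))

    def test_lesion_stage3_gives_constant_output(self, tiny_net, random_clips):
        lesioned = sf.lesion_units(tiny_net, tiny_net.registry.unit_ids("relu3"))
        preds = lesioned.predict(random_clips)
        assert np.allclose(preds, preds[0], atol=1e-5)

    def test_lesion_nondestructive_and_composable(self, tiny_net, random_clips):
        base = tiny_net.predict(random_clips[:4])
        u1 = tiny_net.registry.unit_ids("relu1")[:2]
        u2 = tiny_net.registry.unit_ids("relu2")[:2]
        both = sf.lesion_units(tiny_net, np.concatenate([u1, u2]))
        seq = sf.lesion_units(sf.lesion_units(tiny_net, u1), u2)
        assert np.array_equal(both.predict(random_clips[:4]),
                              seq.predict(random_clips[:4]))
        # idempotent
        twice = sf.lesion_units(both, u1)
        assert np.array_equal(both.predict(random_clips[:4]),
                              twice.predict(random_clips[:4]))
        # original untouched
        assert np.array_equal(base, tiny_net.predict(random_clips[:4]))

    def test_unknown_unit_id(self, tiny_net):
        with pytest.raises(KeyError):
            sf.lesion_units(tiny_net, [10_000])

    def test_lesioned_units_respond_zero(self, tiny_net, random_clips):
        uid = int(tiny_net.registry.unit_ids("relu2")[3])
        lesioned = sf.lesion_units(tiny_net, [uid])
        rec = sf.collect_activations(lesioned, random_clips[:4], "relu2")
        assert np.all(rec.responses[:, 3, :] == 0)


class TestLinearDecoder:
    def test_realizable_targets_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.random((120, 6))
        w = np.array([2.0, -1.0, 0.5, 3.0, 0.0, 1.5])
        y = X @ w + 0.7
        _, rmse = sf.fit_linear_decoder(X, y, epochs=2000, seed=0)
        assert rmse <= 1e-3

    def test_degenerate_activations_warn(self):
        X = np.zeros((20, 3))
        y = np.linspace(0, 1, 20)
        with pytest.warns(UserWarning, match="zero-variance"):
            dec, rmse = sf.fit_linear_decoder(X, y, epochs=10, seed=0)
        assert np.isfinite(rmse)


@pytest.fixture(scope="module")
def fitted(tiny_cfg, random_clips):
    net = sf.build_network(tiny_cfg, seed=4)
    y = np.linspace(1, 16, len(random_clips)).astype(np.float32)
    sf.train(net, random_clips, y, epochs=5, seed=0, lr=1e-3)
    return net, random_clips, y


class TestHeadRetraining:

    def test_prefix_frozen_bit_identical(self, fitted):
        net, clips, y = fitted
        before = [l.W.copy() for l in net.conv1 + net.conv2 + net.conv3]
        model, rmses = sf.retrain_head(net, 4, clips, y, clips, y,
                                       repeats=2, epochs=3, seed=0)
        after = [l.W for l in net.conv1 + net.conv2 + net.conv3]
        for w0, w1 in zip(before, after):
            assert np.abs(w0 - w1).max() == 0
        assert len(rmses) == 2
        assert model.width == 4

    def test_repeats_select_best(self, fitted):
        net, clips, y = fitted
        model, rmses = sf.retrain_head(net, 4, clips, y, clips, y,
                                       repeats=3, epochs=3, seed=1)
        best = float(np.sqrt(np.mean((model.predict(clips) - y) ** 2)))
        assert best == pytest.approx(min(rmses), abs=1e-6)

    def test_invalid_width(self, fitted):
        net, clips, y = fitted
        with pytest.raises(ValueError, match="width"):
            sf.retrain_head(net, 0, clips, y, clips, y)

    def test_scene_head_probability_rows(self, fitted):
        net, clips, _ = fitted
        scenes = np.array([1, 2] * 6)
        acc, auc, pmat, _ = sf.retrain_scene_head(net, clips, scenes, clips,
                                                  scenes, width=8, epochs=8,
                                                  seed=0)
        assert 0.0 <= acc <= 1.0 and 0.0 <= auc <= 1.0
        assert np.allclose(pmat.sum(axis=1), 1.0, atol=1e-6)

    def test_scene_head_single_class_rejected(self, fitted):
        net, clips, _ = fitted
        ones = np.ones(len(clips), dtype=int)
        with pytest.raises(ValueError, match="two classes"):
            sf.retrain_scene_head(net, clips, ones, clips, ones)


class TestEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        est = sf.SlowFusionRegressor(seed=3, channels1=4, channels2=4,
                                     channels3=4, fc4=8, stride1=4, pool1=2,
                                     pool2=1, pool3=1)
        params = est.get_params()
        assert params["channels1"] == 4 and params["seed"] == 3
        est2 = clone(est)
        assert est2.get_params() == params

    def test_fit_predict_roundtrip(self, random_clips):
        est = sf.SlowFusionRegressor(seed=0, channels1=4, channels2=4,
                                     channels3=4, fc4=8, stride1=4, pool1=2,
                                     pool2=1, pool3=1, dropout=0.0,
                                     batch_size=4, momentum=0.8)
        y = np.linspace(1, 16, len(random_clips))
        est.fit(random_clips, y, epochs=2, lr=1e-3)
        preds = est.predict(random_clips)
        assert preds.shape == (len(random_clips),)
        assert np.all(np.isfinite(preds))
        assert len(est.history_) == 2
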