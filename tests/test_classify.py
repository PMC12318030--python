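import numpy as np
import pytest

from lungct import classify, phantom
from lungct.classify import (ClassifierConfig, GaussianNormalizer,
                             build_deep_maxout, build_iln_tl, lehmer_mean,
                             maxout, min_pool, soft_vote, train_ensemble)


class TestLehmerMean:
    def test_constant_input(self):
        assert lehmer_mean(np.array([2.0, 2.0]), 2) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        assert lehmer_mean(np.array([1.0, 2.0, 3.0]), 2) == pytest.approx(14 / 6)

    def test_q_one_is_arithmetic_mean(self, rng):
        x = rng.random(20) + 0.1
        assert lehmer_mean(x, 1) == pytest.approx(x.mean())

    def test_degenerate_denominator_falls_back_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = lehmer_mean(np.array([1.0, -1.0]), 2)
        assert out == pytest.approx(0.0)


class TestGaussianNormalize:
    @pytest.fixture()
    def fitted(self, rng):
        x = rng.random((50, 4)) + 0.5
        return GaussianNormalizer().fit(x), x

    def test_center_maps_to_half(self, fitted):
        norm, _ = fitted
        out = norm.transform(norm.params.mu_l[None, :])
        assert np.allclose(out, 0.5, atol=1e-12)

    def test_plus_three_sigma_maps_to_one(self, fitted):
        norm, _ = fitted
        x = norm.params.mu_l + 3 * norm.params.sigma
        assert np.allclose(norm.transform(x[None, :]), 1.0, atol=1e-12)

    def test_minus_six_sigma_clipped_to_zero(self, fitted):
        norm, _ = fitted
        x = (norm.params.mu_l - 6 * norm.params.sigma)[None, :]
        assert np.allclose(norm.transform(x), 0.0)
        norm.params.clip = False
        assert np.allclose(norm.transform(x), -0.5, atol=1e-12)

    def test_unfitted_rejected(self):
        with pytest.raises(RuntimeError):
            GaussianNormalizer().transform(np.zeros((1, 3)))


class TestMinPool:
    def test_duality_with_max_pool(self, rng):
        g = rng.normal(size=(8, 8))
        expect = -(-g).reshape(4, 2, 4, 2).transpose(0, 2, 1, 3).reshape(4, 4, 4).max(axis=2)
        assert np.allclose(min_pool(g, 2), expect)

    def test_constant_grid(self):
        assert np.allclose(min_pool(np.full((4, 4), 0.3), 2), 0.3)

    def test_direct_window_minimum(self):
        assert min_pool(np.array([[1.0, 2.0], [3.0, 4.0]]), 2)[0, 0] == 1.0

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError):
            min_pool(np.zeros((5, 5)), 2)


class TestMaxout:
    def test_identical_pieces_pass_through(self, rng):
        w = np.tile(rng.normal(size=(1, 3, 4)), (3, 1, 1))
        b = np.zeros((3, 3))
        x = rng.normal(size=4)
        assert np.allclose(maxout(x, w, b), w[0] @ x)

    def test_dominates_each_piece(self, rng):
        w = rng.normal(size=(3, 5, 4))
        b = rng.normal(size=(3, 5))
        x = rng.normal(size=4)
        out = maxout(x, w, b)
        for k in range(3):
            assert np.all(out >= w[k] @ x + b[k] - 1e-12)

    def test_absolute_value_construction(self):
        w = np.array([[[1.0]], [[-1.0]]])
        b = np.zeros((2, 1))
        for x in (-3.0, 0.5, 2.0):
            assert maxout(np.array([x]), w, b)[0] == abs(x)


class TestILNTL:
    def test_forward_probabilities_sum_to_one(self, rng):
        model = build_iln_tl(ClassifierConfig(seed=1), input_size=32)
        imgs = rng.random((3, 32, 32))
        model.normalizer.fit(
            model.trunk_features(imgs).reshape(3, -1))
        probs = model.predict_proba(imgs)
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_depthwise_separable_fewer_parameters_than_full_conv(self):
        model = build_iln_tl(ClassifierConfig(seed=1))
        c = model.trunk.out_channels
        k = model.config.iln.dw_kernel
        dw_params = sum(p.data.size for p in model.dwsep.parameters())
        full_conv = k * k * c * c + c
        assert dw_params < full_conv

    def test_frozen_trunk_unchanged_by_training(self, rng):
        cfg = ClassifierConfig(seed=2)
        cfg.iln.epochs = 2
        model = build_iln_tl(cfg, input_size=32)
        before = model.trunk_digest()
        imgs = rng.random((8, 32, 32))
        labels = np.array([0, 1] * 4)
        model.fit(imgs, labels)
        assert model.trunk_digest() == before


class TestDeepMaxout:
    def test_probabilities_and_determinism(self, rng):
        cfg = ClassifierConfig(seed=3)
        model = build_deep_maxout(cfg)
        x = rng.random((4, 201))
        p1 = model.predict_proba(x)
        p2 = build_deep_maxout(ClassifierConfig(seed=3)).predict_proba(x)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(p1, p2)

    def test_overfits_linearly_separable_vectors(self, rng):
        cfg = ClassifierConfig(seed=4)
        cfg.dm.epochs = 200
        x = rng.normal(size=(16, 201)) * 0.05
        labels = np.array([0, 1] * 8)
        x[:, 7] += labels * 1.0
        model = build_deep_maxout(cfg)
        model.fit(x, labels)
        assert np.mean(model.predict_proba(x).argmax(axis=1) == labels) == 1.0


class TestTrainEnsemble:
    @pytest.fixture(scope="class")
    def small_data(self):
        ds = phantom.generate_dataset(32, 0.5, phantom.PhantomSpec(), seed=5)
        seg_imgs = ds.images * ds.masks
        rng = np.random.default_rng(6)
        feats = rng.normal(size=(32, 201)) * 0.1
        feats[:, 0] += ds.labels * 1.5
        return seg_imgs, feats, ds.labels

    def test_losses_decrease(self, small_data):
        seg_imgs, feats, labels = small_data
        cfg = ClassifierConfig(seed=7)
        cfg.iln.epochs = cfg.dm.epochs = 20
        _, _, hist = train_ensemble(seg_imgs, feats, labels, cfg)
        assert hist["iln"]["loss"][-1] < hist["iln"]["loss"][0]
        assert hist["dm"]["loss"][-1] < hist["dm"]["loss"][0]

    def test_validation_holdout_size(self, small_data):
        seg_imgs, feats, labels = small_data
        cfg = ClassifierConfig(seed=7)
        cfg.iln.epochs = cfg.dm.epochs = 1
        iln, _, hist = train_ensemble(seg_imgs, feats, labels, cfg)
        assert hist["iln"]["n_val"] == round(0.2 * len(labels))

    def test_seeded_rerun_identical_weights(self, small_data):
        seg_imgs, feats, labels = small_data

        def digest():
            cfg = ClassifierConfig(seed=8)
            cfg.iln.epochs = cfg.dm.epochs = 2
            iln, dm, _ = train_ensemble(seg_imgs, feats, labels, cfg)
            import hashlib
            h = hashlib.sha256()
            for p in iln.parameters() + dm.parameters():
                h.update(p.data.tobytes())
            return h.hexdigest()

        assert digest() == digest()

    def test_single_class_rejected(self, small_data):
        seg_imgs, feats, _ = small_data
        with pytest.raises(ValueError):
            train_ensemble(seg_imgs, feats, np.zeros(32, dtype=int))


class TestSoftVote:
    def test_hand_arithmetic_example(self):
        label, fused = soft_vote(np.array([[0.6, 0.4], [0.3, 0.7]]),
                                 np.array([0.5, 0.5]))
        assert np.allclose(fused, [0.45, 0.55])
        assert label == 1

    def test_degenerate_weights_reduce_to_single_classifier(self):
        rows = np.array([[0.9, 0.1], [0.2, 0.8]])
        label, fused = soft_vote(rows, np.array([1.0, 0.0]))
        assert label == 0 and np.allclose(fused, rows[0])

    def test_identical_rows_keep_argmax(self):
        rows = np.array([[0.3, 0.7], [0.3, 0.7]])
        label, _ = soft_vote(rows)
        assert label == 1

    def test_tie_resolves_to_non_cancer(self):
        label, fused = soft_vote(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert label == 0

    def test_fused_probabilities_remain_distribution(self, rng):
        rows = rng.random((2, 2))
        rows /= rows.sum(axis=1, keepdims=True)
        w = rng.random(2)
        w /= w.sum()
        _, fused = soft_vote(rows, w)
        assert fused.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fused >= 0)

    def test_weight_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_vote(np.array([[0.5, 0.5]]), np.array([0.5, 0.5]))
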