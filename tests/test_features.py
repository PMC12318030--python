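import numpy as np
import pytest

from lungct import deepfeat, features, phantom
from lungct.features import (EntropyConfig, GaborParams, LGTrPConfig,
                             PHOGConfig, entropy_weight, extract_feature_vector,
                             gabor_response, gradient_field, improved_entropy,
                             lgtrp_features, ltp_code_map, normalized_entropy,
                             phog_features, shannon_entropy)


class TestGabor:
    def test_zero_image_zero_response(self):
        out = gabor_response(np.zeros((32, 32)), GaborParams())
        assert np.allclose(out, 0.0)

    def test_matched_orientation_beats_orthogonal(self):
        # vertical grating at the filter wavelength: stripes vary along x
        x = np.arange(64)
        grating = 0.5 + 0.5 * np.sin(2 * np.pi * x / 4.0)
        img = np.tile(grating, (64, 1))
        matched = gabor_response(img, GaborParams(orientations=(0.0,)))
        orthogonal = gabor_response(img, GaborParams(orientations=(np.pi / 2,)))
        inner = (slice(8, -8), slice(8, -8))
        assert matched[inner].mean() > 2 * orthogonal[inner].mean()

    def test_dc_invariance(self, nodule_phantom):
        params = GaborParams()
        a = gabor_response(nodule_phantom.image, params)
        b = gabor_response(nodule_phantom.image + 0.17, params)
        assert np.allclose(a, b, atol=1e-10)


def _ltp_center_oracle(patch, L, r1, r2):
    """Scalar walk over directions with independent bilinear sampling."""
    cy = cx = patch.shape[0] // 2
    gc = patch[cy, cx]

    def sample(y, x):
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        dy, dx = y - y0, x - x0
        return ((1 - dy) * (1 - dx) * patch[y0, x0]
                + (1 - dy) * dx * patch[y0, x0 + 1]
                + dy * (1 - dx) * patch[y0 + 1, x0]
                + dy * dx * patch[y0 + 1, x0 + 1])

    code = 0
    for l in range(L):
        ang = 2 * np.pi * l / L
        g1 = sample(cy + r1 * np.sin(ang), cx + r1 * np.cos(ang))
        g2 = sample(cy + r2 * np.sin(ang), cx + r2 * np.cos(ang))
        if g1 > gc and g2 > gc:
            code += 2 ** l
    return code


class TestLTPCodeMap:
    def test_constant_image_all_zero_codes(self):
        codes = ltp_code_map(np.full((16, 16), 0.5), LGTrPConfig())
        assert np.all(codes == 0)

    def test_codes_in_range(self, rng):
        cfg = LGTrPConfig()
        codes = ltp_code_map(rng.random((20, 20)), cfg)
        assert codes.min() >= 0 and codes.max() < 2 ** cfg.directions

    def test_center_code_matches_scalar_walk_oracle(self, rng):
        cfg = LGTrPConfig(directions=8, r1=1.0, r2=2.0)
        # ramp plus jitter; with margin ceil(r2)=2 the 7x7 patch yields a
        # 3x3 valid map whose middle entry is the patch centre
        patch = (np.add.outer(np.arange(7), np.arange(7)) / 12.0
                 + rng.random((7, 7)) * 0.05)
        codes = ltp_code_map(patch, cfg)
        assert codes.shape == (3, 3)
        assert codes[1, 1] == _ltp_center_oracle(patch, 8, 1.0, 2.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ltp_code_map(np.zeros((4, 4)), LGTrPConfig())


class TestLGTrP:
    def test_length_and_block_normalization(self, nodule_phantom):
        vec = lgtrp_features(nodule_phantom.image)
        assert vec.shape == (50,)
        assert np.all(vec >= 0)
        for block in vec.reshape(5, 10):
            assert block.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_constant_offset(self, nodule_phantom):
        a = lgtrp_features(nodule_phantom.image)
        b = lgtrp_features(np.clip(nodule_phantom.image, 0, 0.8) + 0.1)
        c = lgtrp_features(np.clip(nodule_phantom.image, 0, 0.8))
        assert np.allclose(b, c, atol=1e-12)
        assert a.shape == b.shape


class TestGradientField:
    def test_constant_image_zero_magnitude(self):
        f = gradient_field(np.full((8, 8), 0.3))
        assert np.allclose(f.magnitude, 0.0)

    def test_vertical_step_edge_orientation(self):
        img = np.zeros((5, 5))
        img[:, 3:] = 1.0   # vertical edge: gradient along +x
        f = gradient_field(img, "unsigned_180")
        edge = f.orientation[2, 2]
        assert min(edge, np.pi - edge) == pytest.approx(0.0, abs=1e-9)

    def test_magnitude_dominates_components(self, rng):
        img = rng.random((16, 16))
        f = gradient_field(img)
        from scipy import ndimage
        gp = ndimage.sobel(img, axis=1, mode="reflect")
        assert np.all(f.magnitude >= np.abs(gp) - 1e-12)


class TestPHOG:
    def test_length_and_normalization(self, nodule_phantom):
        vec = phog_features(nodule_phantom.image)
        assert vec.shape == (50,)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_level0_matches_direct_histogram_oracle(self, rng):
        img = rng.random((32, 32))
        cfg = PHOGConfig()
        vec = phog_features(img, cfg)
        f = gradient_field(img, cfg.angle_range)
        oracle, _ = np.histogram(f.orientation, bins=cfg.bins,
                                 range=(0.0, np.pi), weights=f.magnitude)
        level0 = vec[:cfg.bins]
        # the pipeline normalises the concatenated vector; compare shapes
        assert np.allclose(level0 / level0.sum(), oracle / oracle.sum(),
                           atol=1e-12)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            phog_features(np.zeros((30, 30)), PHOGConfig(levels=(0, 2)))


class TestEntropyChain:
    def test_shannon_extremes(self):
        assert shannon_entropy(np.full((16, 16), 0.25)) == 0.0
        half = np.zeros((16, 16))
        half[:8] = 1.0
        assert shannon_entropy(half) == pytest.approx(1.0, abs=1e-12)
        cycle = (np.arange(256).repeat(4) / 255.0).reshape(32, 32)
        assert shannon_entropy(cycle) == pytest.approx(8.0, abs=1e-12)

    def test_entropy_weight_values_and_monotonicity(self):
        assert entropy_weight(0.0) == pytest.approx(1.0, abs=1e-12)
        assert entropy_weight(8.0) == pytest.approx(1.99933, abs=1e-5)
        grid = np.linspace(0, 10, 101)
        w = np.array([entropy_weight(e) for e in grid])
        assert np.all(np.diff(w) > 0)
        assert np.all((w >= 1.0) & (w < 2.0))

    def test_normalized_entropy_uniform_support_and_constant(self, rng):
        img = (np.arange(16).repeat(16) / 255.0).reshape(16, 16)
        assert normalized_entropy(img) == pytest.approx(1.0, abs=1e-12)
        assert normalized_entropy(np.full((8, 8), 0.5)) == 0.0

    def test_normalized_entropy_matches_frequency_oracle(self, rng):
        img = rng.integers(0, 256, size=(16, 16)) / 255.0
        q = np.floor(img * 255).astype(int)
        vals, counts = np.unique(q, return_counts=True)
        p = counts / counts.sum()
        oracle = -(p * np.log2(p)).sum() / np.log2(len(vals))
        assert normalized_entropy(img) == pytest.approx(oracle, abs=1e-12)

    def test_improved_entropy_compositional_oracle(self, rng):
        for _ in range(10):
            img = rng.random((12, 12))
            en = shannon_entropy(img)
            nen = normalized_entropy(img)
            w = entropy_weight(en)
            assert improved_entropy(img) == pytest.approx(
                w * en + (1 - w) * nen, abs=1e-12)

    def test_improved_entropy_constant_image_zero(self):
        assert improved_entropy(np.full((8, 8), 0.7)) == 0.0


class TestPCA:
    def test_orthonormal_components_and_evr_ordering(self, rng):
        x = rng.normal(size=(40, 12))
        pca = deepfeat.fit_pca(x, components=6)
        gram = pca.components_ @ pca.components_.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)
        assert np.all(np.diff(pca.explained_variance_) <= 1e-12)

    def test_low_rank_matrix_recovered(self, rng):
        basis = rng.normal(size=(2, 10))
        coeffs = rng.normal(size=(30, 2))
        x = coeffs @ basis
        pca = deepfeat.fit_pca(x, components=3)
        recon = pca.inverse_transform(pca.transform(x))
        assert np.max(np.abs(recon - x)) < 1e-8

    def test_insufficient_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            deepfeat.fit_pca(rng.normal(size=(5, 10)), components=6)


class TestDeepFeatures:
    @pytest.fixture(scope="class")
    def batch(self):
        spec = phantom.PhantomSpec()
        ds = phantom.generate_dataset(120, 0.5, spec, seed=77)
        return ds.images

    def test_output_length_and_determinism(self, batch):
        cfg = deepfeat.DeepFeatConfig(seed=5)
        ex = deepfeat.DeepFeatureExtractor(cfg).fit(batch)
        a = ex(batch[0])
        b = deepfeat.DeepFeatureExtractor(cfg).fit(batch)(batch[0])
        assert a.shape == (100,)
        assert np.array_equal(a, b)

    def test_reconstruction_error_decreases_with_components(self, batch):
        ex = deepfeat.DeepFeatureExtractor(deepfeat.DeepFeatConfig(seed=5))
        raw = np.stack([ex.encode_raw(img) for img in batch])
        errors = []
        for k in (10, 50, 100):
            pca = deepfeat.fit_pca(raw, components=k)
            recon = pca.inverse_transform(pca.transform(raw))
            errors.append(float(np.mean((recon - raw) ** 2)))
        assert errors[0] > errors[1] > errors[2]

    def test_unfitted_extractor_rejected(self, batch):
        ex = deepfeat.DeepFeatureExtractor()
        with pytest.raises(RuntimeError):
            ex(batch[0])


class TestFeatureVector:
    def test_total_length_layout_and_determinism(self, nodule_phantom):
        class FakeDeep:
            def __call__(self, img):
                return np.arange(100, dtype=float)

        fv = extract_feature_vector(nodule_phantom.image, FakeDeep())
        assert fv.vector.shape == (201,)
        lo, hi = fv.layout["phog"]
        assert np.array_equal(fv.vector[lo:hi], fv.phog)
        assert np.array_equal(
            fv.vector,
            extract_feature_vector(nodule_phantom.image, FakeDeep()).vector)

    def test_wrong_segment_length_rejected(self):
        with pytest.raises(ValueError):
            features.FeatureVector201(lgtrp=np.zeros(50), phog=np.zeros(50),
                                      deep=np.zeros(99), ien=0.0)
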