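import numpy as np
import pytest

from mvfcm.views import (Image2D, ViewSpec, build_multiview, contrast_view,
                         default_view_specs, entropy_view, gradient_view,
                         hog_view, intensity_view, median_denoise)


class TestImage2D:
    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            Image2D(np.zeros((2, 5)))

    def test_nonfinite_pixels_rejected(self):
        img = np.zeros((4, 4))
        img[1, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Image2D(img)

    def test_view_spec_validation(self):
        with pytest.raises(ValueError, match="unknown feature"):
            ViewSpec("wavelet")
        with pytest.raises(ValueError, match="radius"):
            ViewSpec("entropy", radius=0)
        with pytest.raises(ValueError, match="bins"):
            ViewSpec("hog", bins=1)


class TestGradient:
    def test_constant_image_has_zero_gradient(self):
        assert np.allclose(gradient_view(np.full((6, 6), 9.0)), 0.0)

    def test_horizontal_ramp_interior_magnitude_is_eight(self):
        # unit-slope ramp: 3x3 Sobel responds with (1+2+1)*2 = 8
        img = np.tile(np.arange(7.0), (7, 1))
        g = gradient_view(img).reshape(7, 7)
        assert np.allclose(g[2:-2, 2:-2], 8.0)

    def test_transpose_swaps_axes(self, rng):
        img = rng.uniform(0, 255, size=(9, 12))
        g = gradient_view(img).reshape(9, 12)
        gt = gradient_view(img.T).reshape(12, 9)
        assert np.allclose(g, gt.T, atol=1e-10)


class TestEntropy:
    def test_constant_image_has_zero_entropy(self):
        assert np.allclose(entropy_view(np.full((8, 8), 42.0), 2), 0.0)

    def test_two_level_window_split_four_five(self):
        # 3x3 window around (1,1) holds 4 pixels of one level, 5 of another
        img = np.zeros((5, 5))
        img[:2, :2] = 10.0
        e = entropy_view(img, 1).reshape(5, 5)
        expected = -(4 / 9) * np.log2(4 / 9) - (5 / 9) * np.log2(5 / 9)
        assert e[1, 1] == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_log2_window_size(self, rng):
        img = rng.integers(0, 256, size=(16, 16)).astype(float)
        e = entropy_view(img, 1)
        assert (e <= np.log2(9) + 1e-12).all()
        assert (e >= 0).all()

    def test_unit_scale_images_are_quantized(self):
        # [0,1] floats quantize to 256 levels, so a two-level image still works
        img = np.zeros((5, 5))
        img[:2, :2] = 0.5
        e = entropy_view(img, 1).reshape(5, 5)
        assert e[1, 1] > 0.9


class TestContrast:
    def test_constant_image_has_zero_contrast(self):
        assert np.allclose(contrast_view(np.full((7, 7), 3.0), 3), 0.0)

    def test_window_range_of_known_values(self):
        img = np.arange(10.0, 100.0, 10.0).reshape(3, 3)
        c = contrast_view(img, 1).reshape(3, 3)
        assert c[1, 1] == pytest.approx(80.0)

    def test_binary_edge_contrast_is_one(self):
        img = np.zeros((6, 6))
        img[:, 3:] = 1.0
        c = contrast_view(img, 1).reshape(6, 6)
        assert np.allclose(c[:, 2:4], 1.0)


class TestHog:
    def test_constant_image_gives_zero_descriptors(self):
        h = hog_view(np.full((8, 8), 5.0), 2, 9)
        assert np.allclose(h, 0.0)

    def test_vertical_edge_concentrates_in_one_bin(self):
        img = np.zeros((9, 9))
        img[:, 4:] = 100.0
        h = hog_view(img, 3, 9).reshape(9, 9, 9)
        center = h[4, 4]
        assert center.argmax() == 0  # horizontal gradient -> 0 deg bin
        assert np.linalg.norm(center) == pytest.approx(1.0, abs=1e-12)
        assert center.max() == pytest.approx(1.0, abs=1e-12)

    def test_rotation_moves_mass_ninety_degrees(self):
        img = np.zeros((9, 9))
        img[:, 4:] = 100.0
        h = hog_view(img, 2, 9).reshape(9, 9, 9)
        hr = hog_view(np.rot90(img), 2, 9).reshape(9, 9, 9)
        b, br = h[4, 4].argmax(), hr[4, 4].argmax()
        n_bins = 9
        assert (br - b) % n_bins == int(round(90 / (180 / n_bins))) % n_bins

    def test_descriptors_non_negative_despite_filter_roundoff(self):
        # large flat regions provoke ~-1e-18 round-off in the window sums
        img = np.zeros((20, 20))
        img[:, 10:] = 200.0
        h = hog_view(img, 3, 9)
        assert (h >= 0).all()

    def test_descriptor_rows_unit_or_zero_norm(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        h = hog_view(img, 1, 6)
        norms = np.linalg.norm(h, axis=1)
        assert ((np.abs(norms - 1) < 1e-9) | (norms == 0)).all()


class TestBuildMultiview:
    def test_paper_views_shapes_on_64x64(self, rng):
        img = rng.uniform(0, 255, size=(64, 64))
        specs = default_view_specs(include_intensity=False)
        data = build_multiview(img, specs)
        assert data.n_views == 4
        assert data.n_samples == 64 * 64
        assert data.view_dims == (9, 1, 1, 1)
        assert data.sample_shape == (64, 64)

    def test_default_includes_intensity_first(self, rng):
        img = rng.uniform(0, 255, size=(16, 16))
        data = build_multiview(img)
        assert data.n_views == 5
        assert data.view_dims[0] == 1

    def test_single_intensity_view_is_zscored_flat_image(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        data = build_multiview(img, [ViewSpec("intensity")])
        flat = img.reshape(-1, 1)
        expected = (flat - flat.mean()) / flat.std()
        assert np.allclose(data.views[0], expected)

    def test_duplicate_specs_give_identical_views(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        data = build_multiview(img, [ViewSpec("gradient"), ViewSpec("gradient")])
        assert np.array_equal(data.views[0], data.views[1])

    def test_all_disabled_rejected(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        with pytest.raises(ValueError, match="no enabled views"):
            build_multiview(img, [ViewSpec("entropy", enabled=False)])

    def test_zero_variance_dimensions_left_at_zero(self):
        data = build_multiview(np.full((8, 8), 7.0))
        for v in data.views:
            assert np.allclose(v, 0.0)

    @pytest.mark.parametrize("feature", ["gradient", "entropy", "contrast"])
    def test_translation_consistency_in_interior(self, rng, feature):
        """Shifting the image content shifts the interior feature map."""
        from mvfcm import views as V
        fn = {"gradient": V.gradient_view, "entropy": V.entropy_view,
              "contrast": V.contrast_view}[feature]
        base = rng.uniform(0, 255, size=(14, 14))
        shifted = np.roll(base, 2, axis=1)
        kw = {} if feature == "gradient" else {"window_radius": 1}
        a = fn(base, **kw).reshape(14, 14)
        b = fn(shifted, **kw).reshape(14, 14)
        assert np.allclose(a[3:-3, 3:-5], b[3:-3, 5:-3], atol=1e-9)


def test_median_denoise_removes_salt_noise():
    img = np.full((9, 9), 50.0)
    img[4, 4] = 255.0
    out = median_denoise(img).pixels
    assert out[4, 4] == 50.0
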