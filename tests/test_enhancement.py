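"""Enhancement operators against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammofusion import enhancement as E
from mammofusion.errors import InvalidConfigError, InvalidInputError


# ---------------------------------------------------------------------------
# independent oracles (direct per-pixel evaluation, no shared code paths)
# ---------------------------------------------------------------------------


def he_oracle(pixels: np.ndarray, levels: int = 256) -> np.ndarray:
    """Histogram equalization by direct per-pixel CDF evaluation."""
    flat = pixels.ravel()
    n = flat.size
    out = np.empty(n, dtype=np.int64)
    for i, v in enumerate(flat):
        cdf = np.count_nonzero(flat <= v) / n
        out[i] = math.floor((levels - 1) * cdf + 0.5)
    return out.reshape(pixels.shape)


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def blur_oracle(img: np.ndarray, sigma: float) -> np.ndarray:
    """Direct 2-D convolution with a sampled Gaussian, symmetric padding."""
    k1 = gaussian_kernel_1d(sigma)
    r = (k1.size - 1) // 2
    kernel = np.outer(k1, k1)
    padded = np.pad(np.asarray(img, dtype=float), r, mode="symmetric")
    H, W = img.shape
    out = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            out[i, j] = np.sum(padded[i : i + 2 * r + 1, j : j + 2 * r + 1] * kernel)
    return out


# ---------------------------------------------------------------------------
# histogram / transfer map / equalize
# ---------------------------------------------------------------------------


class TestHistogram:
    def test_single_level_image(self):
        hist = E.compute_histogram(E.GrayImage(np.zeros((2, 2), dtype=int)))
        assert hist.counts[0] == 4
        assert hist.normalized[0] == 1.0
        assert np.allclose(hist.cumulative, 1.0)

    def test_hand_counted_example(self):
        hist = E.compute_histogram(E.GrayImage(np.array([[0, 0], [128, 255]])))
        assert hist.normalized[0] == 0.5
        assert hist.normalized[128] == 0.25
        assert hist.normalized[255] == 0.25
        assert hist.cumulative[0] == 0.5
        assert hist.cumulative[128] == 0.75
        assert hist.cumulative[255] == 1.0

    def test_counts_conservation_and_cdf_shape(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(7, 5)))
        hist = E.compute_histogram(img)
        assert hist.counts.sum() == 35
        assert abs(hist.normalized.sum() - 1.0) < 1e-9
        assert np.all(np.diff(hist.cumulative) >= -1e-15)
        assert abs(hist.cumulative[-1] - 1.0) < 1e-9

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidInputError):
            E.GrayImage(np.zeros((0, 3), dtype=int))


class TestEqualize:
    def test_transfer_map_example(self):
        hist = E.compute_histogram(E.GrayImage(np.array([[0, 0], [128, 255]])))
        lut = E.equalization_map(hist, 256).lut
        assert (lut[0], lut[128], lut[255]) == (128, 191, 255)

    def test_constant_image_maps_to_top_level(self):
        out = E.equalize(E.GrayImage(np.full((3, 3), 42)))
        assert np.all(out.pixels == 255)

    def test_flat_histogram_is_near_fixed_point(self):
        img = E.GrayImage(np.arange(256, dtype=int).reshape(16, 16))
        out = E.equalize(img)
        # HE of a perfectly flat histogram is the identity within rounding
        assert np.max(np.abs(out.pixels - img.pixels)) <= 1

    def test_small_example_composition(self):
        out = E.equalize(E.GrayImage(np.array([[0, 0], [128, 255]])))
        assert np.array_equal(out.pixels, [[128, 128], [191, 255]])

    def test_ordering_preserved_and_in_range(self, rng):
        px = rng.integers(0, 256, size=(8, 8))
        out = E.equalize(E.GrayImage(px)).pixels
        assert out.min() >= 0 and out.max() <= 255
        flat_in, flat_out = px.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order]) >= 0)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        n_rows=st.integers(1, 8),
        n_cols=st.integers(1, 8),
        levels=st.lists(st.integers(0, 255), min_size=1, max_size=4, unique=True),
        data=st.data(),
    )
    def test_matches_per_pixel_oracle_on_small_images(self, n_rows, n_cols, levels, data):
        """equalize == direct CDF evaluation on <=8x8 images with <=4 levels."""
        idx = data.draw(
            st.lists(
                st.integers(0, len(levels) - 1),
                min_size=n_rows * n_cols,
                max_size=n_rows * n_cols,
            )
        )
        px = np.array(levels, dtype=np.int64)[idx].reshape(n_rows, n_cols)
        assert np.array_equal(E.equalize(E.GrayImage(px)).pixels, he_oracle(px))


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------


class TestClahe:
    def test_single_tile_nonbinding_clip_reduces_to_global_he(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(12, 9)))
        cfg = E.ClaheConfig(tile_grid=(1, 1), clip_factor=float(img.levels))
        assert np.array_equal(E.clahe(img, cfg).pixels, E.equalize(img).pixels)

    @pytest.mark.parametrize("clip_factor", [0.5, 1.0, 2.0, 7.3])
    def test_clip_redistribution_conserves_mass(self, rng, clip_factor):
        counts = rng.integers(0, 40, size=256)
        clip_limit = clip_factor * counts.sum() / 256
        redistributed = E.clip_redistribute(counts, clip_limit)
        assert redistributed.sum() == counts.sum()
        assert np.all(redistributed >= 0)

    def test_per_tile_mode_matches_isolated_tile_equalization(self, rng):
        px = rng.integers(0, 256, size=(4, 4))
        cfg = E.ClaheConfig(tile_grid=(2, 2), clip_factor=1e9, interpolation="none")
        got = E.clahe(E.GrayImage(px), cfg).pixels
        expected = np.empty_like(px)
        for ti in range(2):
            for tj in range(2):
                sl = (slice(2 * ti, 2 * ti + 2), slice(2 * tj, 2 * tj + 2))
                expected[sl] = he_oracle(px[sl])
        assert np.array_equal(got, expected)

    def test_output_in_range_with_binding_clip(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(32, 32)))
        out = E.clahe(img, E.ClaheConfig(tile_grid=(4, 4), clip_factor=2.0))
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255
        assert out.shape == img.shape

    def test_tile_grid_larger_than_image_rejected(self):
        img = E.GrayImage(np.zeros((4, 4), dtype=int))
        with pytest.raises(InvalidConfigError):
            E.clahe(img, E.ClaheConfig(tile_grid=(8, 8)))


# ---------------------------------------------------------------------------
# inversion and sharpening
# ---------------------------------------------------------------------------


class TestInvert:
    def test_extremes_and_midpoint(self):
        img = E.GrayImage(np.array([[0, 100], [255, 42]]))
        out = E.invert(img).pixels
        assert out[0, 0] == 255
        assert out[0, 1] == 155
        assert out[1, 0] == 0

    def test_involution(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(6, 11)))
        assert np.array_equal(E.invert(E.invert(img)).pixels, img.pixels)


class TestFiltering:
    def test_low_pass_fixes_constants_and_preserves_mean(self, rng):
        const = np.full((9, 9), 73.0)
        assert np.allclose(E.low_pass(const, 2.0), 73.0)
        img = rng.integers(0, 256, size=(15, 11)).astype(float)
        out = E.low_pass(img, 1.7)
        assert abs(out.mean() - img.mean()) <= 1e-6 * img.mean()

    def test_low_pass_impulse_response_is_gaussian_kernel(self):
        sigma = 1.2
        k1 = gaussian_kernel_1d(sigma)
        r = (k1.size - 1) // 2
        size = 4 * r + 1
        impulse = np.zeros((size, size))
        impulse[size // 2, size // 2] = 1.0
        out = E.low_pass(impulse, sigma)
        center = out[size // 2 - r : size // 2 + r + 1, size // 2 - r : size // 2 + r + 1]
        assert np.allclose(center, np.outer(k1, k1), atol=1e-12)

    def test_high_pass_constant_is_zero_and_sums_back(self, rng):
        assert np.allclose(E.high_pass(np.full((5, 5), 9.0), 1.0), 0.0)
        img = rng.integers(0, 256, size=(10, 10)).astype(float)
        assert np.allclose(E.high_pass(img, 2.0) + E.low_pass(img, 2.0), img)

    def test_high_pass_step_edge_antisymmetric(self):
        step = np.tile(np.array([0.0] * 4 + [100.0] * 4), (8, 1))
        hp = E.high_pass(step, 1.0)
        # response is antisymmetric about the edge between columns 3 and 4
        assert np.allclose(hp[:, :4], -hp[:, 7:3:-1], atol=1e-9)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(InvalidConfigError):
            E.low_pass(np.zeros((3, 3)), 0.0)


class TestHighBoost:
    def test_a_equals_one_is_clipped_high_pass(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(8, 8)))
        hb = E.high_boost(img, A=1.0, sigma=1.5).pixels
        hp = np.clip(np.floor(E.high_pass(img, 1.5) + 0.5), 0, 255)
        assert np.array_equal(hb, hp.astype(int))

    def test_constant_image_with_a_two_is_unchanged(self):
        img = E.GrayImage(np.full((7, 7), 88))
        assert np.array_equal(E.high_boost(img, A=2.0, sigma=1.0).pixels, img.pixels)

    def test_matches_brute_force_convolution_oracle(self, rng):
        px = rng.integers(0, 256, size=(8, 8))
        A, sigma = 1.5, 1.3
        boosted = A * px - blur_oracle(px, sigma)
        expected = np.clip(np.floor(boosted + 0.5), 0, 255).astype(int)
        assert np.array_equal(E.high_boost(E.GrayImage(px), A=A, sigma=sigma).pixels, expected)

    def test_both_printed_forms_agree_before_clipping(self, rng):
        img = rng.integers(0, 256, size=(9, 9)).astype(float)
        A, sigma = 1.7, 2.1
        form_a = A * img - E.low_pass(img, sigma)
        form_b = (A - 1.0) * img + E.high_pass(img, sigma)
        assert np.allclose(form_a, form_b, atol=1e-9)


# ---------------------------------------------------------------------------
# fusion pipeline
# ---------------------------------------------------------------------------


class TestFusion:
    def test_empty_recipe_is_identity(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(5, 5)))
        out = E.apply_fusion(img, E.FusionConfig())
        assert np.array_equal(out.pixels, img.pixels)

    def test_double_inversion_is_identity(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(5, 5)))
        cfg = E.FusionConfig(steps=(E.InvertStep(), E.InvertStep()))
        assert np.array_equal(E.apply_fusion(img, cfg).pixels, img.pixels)

    def test_degenerate_clahe_step_is_global_he(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(6, 6)))
        cfg = E.FusionConfig(
            steps=(E.ClaheStep(E.ClaheConfig(tile_grid=(1, 1), clip_factor=1e9)),)
        )
        assert np.array_equal(E.apply_fusion(img, cfg).pixels, E.equalize(img).pixels)

    def test_default_recipe_and_name_parsing(self, rng):
        img = E.GrayImage(rng.integers(0, 256, size=(16, 16)))
        cfg = E.FusionConfig.from_names(["clahe", "invert", "highboost"])
        out = E.apply_fusion(img, cfg)
        assert out.shape == img.shape
        with pytest.raises(InvalidConfigError):
            E.FusionConfig.from_names(["sharpen"])
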