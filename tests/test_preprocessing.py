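"""Preprocessing chain: oracles for resize/blur/unsharp, CLAHE behavior,
and the train-only standardization guard."""

import numpy as np
import pytest
import skimage.color as skcolor

from lsetnet import (
    ChannelStats,
    ImageRecord,
    LeakageError,
    PreprocConfig,
    clahe_l_channel,
    gaussian_blur,
    fit_channel_stats,
    preprocess_pipeline,
    resize_image,
    standardize,
    unsharp_mask,
)
from lsetnet.preprocessing import enhance, gaussian_kernel_1d


def _naive_bilinear(img, size):
    """Independent bilinear-resize oracle (center-aligned, edge-clamped)."""
    h, w, _ = img.shape
    out = np.zeros((size, size, 3))
    for i in range(size):
        for j in range(size):
            y = min(max((i + 0.5) * h / size - 0.5, 0), h - 1)
            x = min(max((j + 0.5) * w / size - 0.5, 0), w - 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (img[y0, x0] * (1 - fy) * (1 - fx) + img[y0, x1] * (1 - fy) * fx
                         + img[y1, x0] * fy * (1 - fx) + img[y1, x1] * fy * fx)
    return out


class TestResize:
    def test_shape_contract(self):
        img = np.random.default_rng(0).integers(0, 255, (496, 496, 3), dtype=np.uint8)
        assert resize_image(img, 248).shape == (248, 248, 3)

    def test_identity_at_target_size(self):
        img = np.random.default_rng(1).integers(0, 255, (248, 248, 3), dtype=np.uint8)
        assert np.array_equal(resize_image(img, 248), img)

    def test_matches_bilinear_stencil(self):
        img = np.zeros((2, 2, 3))
        img[0, 0] = 255.0
        img[1, 1] = 255.0
        got = resize_image(img, 4)
        assert np.allclose(got, _naive_bilinear(img, 4), atol=1e-9)

    def test_zero_size_fatal(self):
        with pytest.raises(ValueError):
            resize_image(np.zeros((4, 4, 3), np.uint8), 0)


class TestCLAHE:
    def test_constant_stays_spatially_constant(self):
        img = np.full((60, 60, 3), 120, np.uint8)
        out = clahe_l_channel(img)
        assert out.dtype == np.uint8
        assert np.all(out == out[0, 0])

    def test_output_in_8bit_range(self, rng):
        img = rng.integers(0, 255, (100, 100, 3), dtype=np.uint8)
        out = clahe_l_channel(img)
        assert out.dtype == np.uint8  # range enforced by dtype

    def test_low_contrast_texture_std_increases(self, rng):
        # low-contrast ramp with mild local texture: the configured clip
        # limit amplifies local contrast markedly
        ramp = np.tile(np.linspace(118, 138, 248)[None, :], (248, 1))
        ch = np.clip(ramp + 2 * rng.standard_normal((248, 248)), 0, 255).astype(np.uint8)
        img = np.repeat(ch[..., None], 3, axis=2)
        l_before = skcolor.rgb2lab(img / 255.0)[..., 0].std()
        l_after = skcolor.rgb2lab(clahe_l_channel(img) / 255.0)[..., 0].std()
        assert l_after > l_before

    def test_tiny_image_shrinks_tiles(self, caplog):
        img = np.random.default_rng(3).integers(0, 255, (8, 8, 3), dtype=np.uint8)
        out = clahe_l_channel(img)  # must not raise
        assert out.shape == (8, 8, 3)


class TestGaussianBlur:
    def test_constant_is_fixed_point(self):
        img = np.full((32, 32, 3), 90, np.uint8)
        assert np.array_equal(gaussian_blur(img), img)

    def test_impulse_response_equals_kernel(self):
        img = np.zeros((31, 31, 3))
        img[15, 15, :] = 1.0
        out = gaussian_blur(img, 9, 2.0)
        k1 = gaussian_kernel_1d(9, 2.0)
        expected = np.outer(k1, k1)
        assert np.allclose(out[11:20, 11:20, 0], expected, atol=1e-12)

    def test_shift_equivariance_in_interior(self, rng):
        img = rng.random((40, 40, 3))
        shifted = np.roll(img, 3, axis=1)
        a = gaussian_blur(img, 9, 2.0)
        b = gaussian_blur(shifted, 9, 2.0)
        assert np.allclose(np.roll(a, 3, axis=1)[:, 10:30], b[:, 10:30], atol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((8, 8, 3)), kernel=8)


class TestUnsharp:
    def test_constant_unchanged(self):
        img = np.full((20, 20, 3), 77, np.uint8)
        assert np.array_equal(unsharp_mask(img), img)

    def test_step_edge_overshoot_matches_1d_stencil(self):
        # 1-D analytic profile: out = (1+a)x - a*blur(x) on a step
        step = np.zeros((1, 64, 3))
        step[:, 32:, :] = 200.0
        alpha, k, sigma = 1.8, 7, 0.3 * ((7 - 1) / 2 - 1) + 0.8
        k1 = gaussian_kernel_1d(k, sigma)
        row = step[0, :, 0]
        blurred = np.convolve(np.pad(row, (3, 3), mode="reflect"), k1, mode="valid")
        expected = np.clip((1 + alpha) * row - alpha * blurred, 0, 255)
        got = unsharp_mask(step, alpha, k, sigma)[0, :, 0]
        assert np.allclose(got, expected, atol=1e-9)


class TestChannelStats:
    def test_hand_computed_moments(self):
        a = np.zeros((2, 2, 3), np.uint8)
        b = np.full((2, 2, 3), 100, np.uint8)
        st = fit_channel_stats([a, b], enhanced=False)
        assert np.allclose(st.mu, 50.0)
        assert np.allclose(st.sigma, 50.0)

    def test_non_train_record_fatal(self, leaf_folder):
        root, manifest = leaf_folder
        rec = manifest.records[0]
        val_rec = ImageRecord(rec.image_id, rec.path, rec.label, split="val",
                              parent_id=rec.image_id)
        with pytest.raises(LeakageError):
            fit_channel_stats([val_rec])

    def test_sigma_floored_for_constant_input(self):
        img = np.full((4, 4, 3), 128, np.uint8)
        st = fit_channel_stats([img], enhanced=False)
        assert np.allclose(st.mu, 128.0)
        assert np.all(st.sigma >= 1e-6)

    def test_stats_text_roundtrip(self, tmp_path):
        st = ChannelStats(mu=[1.5, 2.5, 3.5], sigma=[0.1, 0.2, 0.3])
        st.save(tmp_path / "s.csv")
        back = ChannelStats.load(tmp_path / "s.csv")
        assert np.array_equal(back.mu, st.mu)
        assert np.array_equal(back.sigma, st.sigma)


class TestStandardize:
    def test_at_mu_gives_zero_and_unit_identity(self):
        st = ChannelStats(mu=[10, 20, 30], sigma=[1, 1, 1])
        img = np.broadcast_to(np.array([10.0, 20.0, 30.0]), (4, 4, 3))
        assert np.allclose(standardize(img, st), 0.0)
        ident = ChannelStats(mu=[0, 0, 0], sigma=[1, 1, 1])
        x = np.random.default_rng(0).random((4, 4, 3))
        assert np.allclose(standardize(x, ident), x)

    def test_training_split_self_consistency(self, rng):
        imgs = [rng.integers(0, 255, (16, 16, 3), dtype=np.uint8) for _ in range(5)]
        st = fit_channel_stats(imgs, enhanced=False)
        z = np.concatenate([standardize(i, st).reshape(-1, 3) for i in imgs])
        assert np.abs(z.mean(axis=0)).max() < 1e-6
        assert np.abs(z.std(axis=0) - 1).max() < 1e-6


class TestPipeline:
    def test_constant_image_zeros_after_standardization(self):
        cfg = PreprocConfig(target_size=32)
        img = np.full((40, 40, 3), 100, np.uint8)
        enhanced = enhance(img, cfg)
        assert np.all(enhanced == enhanced[0, 0])  # constant survives the chain
        st = fit_channel_stats([enhanced], enhanced=False)
        out = preprocess_pipeline(img, cfg, st)
        assert np.abs(out).max() < 1e-6

    def test_batch_order_preserved(self, leaf_arrays):
        X, _, _ = leaf_arrays
        cfg = PreprocConfig(target_size=32)
        outs = [preprocess_pipeline(x, cfg) for x in X[:3]]
        again = [preprocess_pipeline(x, cfg) for x in X[:3]]
        for a, b in zip(outs, again):
            assert np.array_equal(a, b)
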