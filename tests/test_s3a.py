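"""Photometric artifact transforms and class balancing."""

import numpy as np
import pytest

from cytofuse.datatypes import ImageRecord, LabeledImageSet
from cytofuse.s3a import (
    apply_artifact_chain,
    balance_dataset,
    brightness,
    contrast,
    gaussian_blur,
    gaussian_noise,
    pixel_dropout,
    replay_chain,
    salt_pepper,
)


def uniform(value, size=32, label="x"):
    return ImageRecord(pixels=np.full((size, size, 3), value, np.uint8), label=label)


class TestBrightness:
    def test_identity_at_alpha_one(self, gray_image):
        assert np.array_equal(brightness(gray_image, 1.0).pixels, gray_image.pixels)

    def test_linear_scaling(self):
        assert (brightness(uniform(100), 1.12).pixels == 112).all()

    def test_matches_scale_then_clip_oracle(self, rng):
        px = rng.integers(0, 256, (20, 20, 3)).astype(np.uint8)
        img = ImageRecord(pixels=px, label="x")
        expected = np.clip(np.rint(px.astype(float) * 1.12), 0, 255)
        out = brightness(img, 1.12)
        assert np.array_equal(out.pixels, expected.astype(np.uint8))
        assert out.pixels[px == 240].min() == 255  # saturation case


class TestContrast:
    def test_identity_at_beta_one(self, gray_image):
        assert np.array_equal(contrast(gray_image, 1.0).pixels, gray_image.pixels)

    def test_uniform_image_is_fixed_point(self):
        for beta in (0.85, 1.0, 1.2):
            assert (contrast(uniform(77), beta).pixels == 77).all()

    def test_two_level_image_by_hand(self):
        px = np.full((16, 16, 3), 50, np.uint8)
        px[:8] = 150  # mean = 100
        out = contrast(ImageRecord(pixels=px, label="x"), 1.2)
        assert set(np.unique(out.pixels)) == {40, 160}


class TestGaussianNoise:
    def test_noise_std_close_to_five(self, gray_image, rng):
        noisy = gaussian_noise(gray_image, rng=rng)
        diff = noisy.pixels.astype(float) - gray_image.pixels.astype(float)
        assert diff.std() == pytest.approx(5.0, rel=0.05)
        assert abs(diff.mean()) < 3 * 5.0 / np.sqrt(diff.size)

    def test_zero_sigma_identity(self, gray_image, rng):
        assert np.array_equal(
            gaussian_noise(gray_image, sigma=0.0, rng=rng).pixels, gray_image.pixels
        )


class TestSaltPepper:
    def test_altered_fraction_and_codomain(self, gray_image, rng):
        out = salt_pepper(gray_image, rng=rng)
        changed = out.pixels != gray_image.pixels
        frac = changed.any(axis=2).mean()
        n = gray_image.pixels.shape[0] * gray_image.pixels.shape[1]
        sigma = np.sqrt(0.004 * 0.996 / n)
        assert abs(frac - 0.004) < 3 * sigma
        assert set(np.unique(out.pixels[changed])) <= {0, 255}

    def test_zero_rho_identity(self, gray_image, rng):
        assert np.array_equal(
            salt_pepper(gray_image, rho=0.0, rng=rng).pixels, gray_image.pixels
        )


class TestGaussianBlur:
    def test_uniform_fixed_point(self, gray_image):
        assert np.array_equal(gaussian_blur(gray_image).pixels, gray_image.pixels)

    def test_mean_preserved_with_reflective_border(self, rng):
        px = rng.integers(0, 256, (40, 40, 3)).astype(np.uint8)
        img = ImageRecord(pixels=px, label="x")
        out = gaussian_blur(img)
        assert abs(out.pixels.mean() - px.mean()) < 1.0

    def test_impulse_spreads_to_3x3_only(self):
        px = np.zeros((21, 21, 3), np.uint8)
        px[10, 10] = 255
        out = gaussian_blur(ImageRecord(pixels=px, label="x")).pixels[:, :, 0]
        lit = np.argwhere(out > 0)
        assert lit.min() >= 9 and lit.max() <= 11
        assert out[9:12, 9:12].min() > 0


class TestPixelDropout:
    def test_zeroed_fraction(self, gray_image, rng):
        out = pixel_dropout(gray_image, rng=rng)
        frac = (out.pixels == 0).all(axis=2).mean()
        n = gray_image.pixels.shape[0] * gray_image.pixels.shape[1]
        sigma = np.sqrt(0.005 * 0.995 / n)
        assert abs(frac - 0.005) < 3 * sigma

    def test_extremes(self, gray_image, rng):
        assert np.array_equal(
            pixel_dropout(gray_image, p_d=0.0, rng=rng).pixels, gray_image.pixels
        )
        assert (pixel_dropout(gray_image, p_d=1.0, rng=rng).pixels == 0).all()


class TestChain:
    def test_same_seed_same_output_and_params(self, tiny4):
        img = tiny4[0]
        o1, p1 = apply_artifact_chain(img, np.random.default_rng(4))
        o2, p2 = apply_artifact_chain(img, np.random.default_rng(4))
        assert np.array_equal(o1.pixels, o2.pixels)
        assert p1.describe() == p2.describe()
        assert o1.source == "augmented"

    def test_replay_reproduces_chain_bit_exactly(self, tiny4):
        for seed in range(10):
            img = tiny4[seed % len(tiny4)]
            out, params = apply_artifact_chain(img, np.random.default_rng(seed))
            assert np.array_equal(replay_chain(img, params).pixels, out.pixels)

    def test_chain_length_one_to_three_distinct(self, tiny4):
        for seed in range(20):
            _, params = apply_artifact_chain(tiny4[0], np.random.default_rng(seed))
            names = [n for n, _ in params.chain]
            assert 1 <= len(names) <= 3
            assert len(set(names)) == len(names)

    def test_outputs_remain_valid_8bit_same_shape(self, tiny4):
        img = tiny4[3]
        out, _ = apply_artifact_chain(img, np.random.default_rng(8))
        assert out.pixels.dtype == np.uint8
        assert out.pixels.shape == img.pixels.shape


class TestBalance:
    def make(self, counts, size=32):
        recs = []
        for cls, n in counts.items():
            for i in range(n):
                px = np.full((size, size, 3), 100 + (i % 50), np.uint8)
                recs.append(
                    ImageRecord(pixels=px, label=cls, source="file", ident=f"{cls}/{i:05d}.png")
                )
        return LabeledImageSet(recs)

    def test_minority_augmented_majority_truncated(self):
        data = self.make({"small": 7, "big": 25})
        balanced, plan = balance_dataset(data, target=10, rng=0)
        assert balanced.class_counts() == {"small": 10, "big": 10}
        # all minority originals retained
        small_idents = {r.ident for r in balanced.by_class("small")}
        assert {f"small/{i:05d}.png" for i in range(7)} <= small_idents
        # majority keeps exactly the first 10 in lexicographic order
        big_idents = sorted(r.ident for r in balanced.by_class("big"))
        assert big_idents == [f"big/{i:05d}.png" for i in range(10)]
        assert plan.per_class_deficit == {"small": 3, "big": 0}
        assert plan.per_class_retained == {"small": 7, "big": 10}

    def test_exact_target_class_unchanged(self):
        data = self.make({"a": 10, "b": 3})
        balanced, _ = balance_dataset(data, target=10, rng=0)
        assert sorted(r.ident for r in balanced.by_class("a")) == sorted(
            r.ident for r in data.by_class("a")
        )

    def test_reproducible_given_master_seed(self):
        data = self.make({"a": 4, "b": 9})
        b1, _ = balance_dataset(data, target=12, rng=99)
        b2, _ = balance_dataset(data, target=12, rng=99)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(b1, b2))
        assert [r.ident for r in b1] == [r.ident for r in b2]

    def test_errors(self):
        data = self.make({"a": 4})
        with pytest.raises(ValueError):
            balance_dataset(data, target=0, rng=0)
        with pytest.raises(ValueError):
            balance_dataset(LabeledImageSet([]), target=5, rng=0)
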