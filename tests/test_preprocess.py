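"""Preprocessing operators: printed-formula values, range contracts, purity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonyqc.exceptions import ParameterError, ValidationError
from colonyqc.image import ColonyImage
from colonyqc.preprocess import (PreprocessSpec, binarize, equalize_histogram,
                                 minmax_normalize, resize_to_input, to_gray)


def img_from(arr, rng="float01", um=(1.0, 1.0)):
    return ColonyImage(pixels=np.asarray(arr, dtype=np.float64),
                       intensity_range=rng, um_per_px=um)


def random_img(seed, shape=(16, 16)):
    return img_from(np.random.default_rng(seed).random(shape))


class TestResize:
    def test_camera_geometry_bookkeeping(self):
        """1280x960 px at 0.2266 µm/px resized to 256: µm/px scales per axis."""
        um = 290.0 / 1280.0
        img = img_from(np.zeros((960, 1280)), um=(um, um))
        out = resize_to_input(img, 256)
        assert out.pixels.shape == (256, 256)
        assert out.um_per_px[1] == pytest.approx(um * 1280 / 256)
        assert out.um_per_px[0] == pytest.approx(um * 960 / 256)
        # the physical field of view is unchanged
        assert out.extent_um == pytest.approx(img.extent_um)

    def test_identity_when_already_target(self):
        img = random_img(0, (256, 256))
        out = resize_to_input(img, 256)
        assert np.array_equal(out.pixels, img.pixels)

    def test_one_pixel_input_gives_constant(self):
        out = resize_to_input(img_from([[0.7]]), 256)
        assert out.pixels.shape == (256, 256)
        assert np.allclose(out.pixels, 0.7)

    def test_exact_local_mean_when_downscaling_by_two(self):
        x = np.arange(64.0).reshape(8, 8) / 64.0
        x16 = np.kron(x, np.ones((2, 2)))
        down = resize_to_input(img_from(x16), 8)
        assert np.allclose(down.pixels, x)


class TestToGray:
    def test_gray_fixed_point(self):
        px = np.full((2, 2, 3), 100.0)
        out = to_gray(img_from(px, rng="uint8"))
        assert np.allclose(out.pixels, 100.0)

    @pytest.mark.parametrize("rgb,expected", [
        ((255, 0, 0), 76.245),   # 0.299 * 255
        ((0, 0, 255), 29.07),    # 0.114 * 255
        ((0, 255, 0), 149.685),  # 0.587 * 255
    ])
    def test_printed_luma_formula(self, rgb, expected):
        px = np.tile(np.array(rgb, dtype=float), (2, 2, 1))
        out = to_gray(img_from(px, rng="uint8"))
        assert out.pixels == pytest.approx(expected)

    def test_grayscale_passthrough(self):
        img = random_img(1)
        assert to_gray(img) is img

    def test_output_within_uint8_range(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 256, size=(8, 8, 3)).astype(float)
        out = to_gray(img_from(px, rng="uint8"))
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255


class TestMinMax:
    def test_hand_values(self):
        out = minmax_normalize(img_from(np.array([[0.0, 128.0, 255.0]]),
                                        rng="uint8"))
        assert np.allclose(out.pixels, [[0.0, 128 / 255, 1.0]])

    def test_constant_maps_to_zero(self):
        out = minmax_normalize(img_from(np.full((4, 4), 0.3)))
        assert np.array_equal(out.pixels, np.zeros((4, 4)))

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_idempotent_and_in_range(self, seed):
        img = random_img(seed)
        once = minmax_normalize(img)
        twice = minmax_normalize(once)
        assert np.allclose(once.pixels, twice.pixels)
        assert once.pixels.min() >= 0 and once.pixels.max() <= 1


class TestBinarize:
    def test_boundary_inclusive(self):
        out = binarize(img_from(np.array([[0.2, 0.5, 0.8], [0.0, 1.0, 0.3]])),
                       threshold=0.5)
        # after min-max on [0,1]-spanning input the values are unchanged
        assert np.array_equal(out.pixels[0], [0, 1, 1])

    def test_all_zero_stays_zero(self):
        out = binarize(img_from(np.zeros((4, 4))), threshold=0.7)
        assert not out.pixels.any()

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_idempotent_binary_output(self, seed):
        img = random_img(seed)
        once = binarize(img, 0.4)
        twice = binarize(once, 0.4)
        assert set(np.unique(once.pixels)) <= {0.0, 1.0}
        assert np.array_equal(once.pixels, twice.pixels)

    def test_otsu_default_splits_bimodal(self):
        px = np.concatenate([np.full(32, 0.1), np.full(32, 0.9)]).reshape(8, 8)
        out = binarize(img_from(px), "otsu")
        assert out.pixels.sum() == 32

    def test_threshold_out_of_range(self):
        with pytest.raises(ParameterError):
            binarize(random_img(0), threshold=1.5)


class TestEqualize:
    def test_two_valued_cdf_remap(self):
        """Half the pixels at 10, half at 200 -> CDF values {0.5, 1.0}."""
        px = np.concatenate([np.full(32, 10.0), np.full(32, 200.0)]).reshape(8, 8)
        out = equalize_histogram(img_from(px, rng="uint8"))
        vals = np.unique(out.pixels)
        assert vals == pytest.approx([0.5, 1.0])

    def test_uniform_histogram_fixed_point(self):
        px = np.arange(256.0).reshape(16, 16)
        out = equalize_histogram(img_from(px, rng="uint8"))
        expected = minmax_normalize(img_from(px, rng="uint8")).pixels
        assert np.allclose(out.pixels, expected, atol=1 / 256 + 1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_monotone_and_unit_range(self, seed):
        img = random_img(seed)
        out = equalize_histogram(img)
        a = img.pixels.ravel()
        b = out.pixels.ravel()
        order = np.argsort(a, kind="stable")
        assert np.all(np.diff(b[order]) >= -1e-12)
        assert b.min() >= 0 and b.max() <= 1


class TestPurityAndSpec:
    def test_operators_do_not_mutate_input(self):
        img = random_img(5)
        before = img.pixels.copy()
        for op in (minmax_normalize, equalize_histogram,
                   lambda i: binarize(i, 0.5), lambda i: resize_to_input(i, 8)):
            op(img)
            assert np.array_equal(img.pixels, before)

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            PreprocessSpec(method="sharpen")
        with pytest.raises(ParameterError):
            PreprocessSpec(method="binarize", binarize_threshold=2.0)
        with pytest.raises(ValueError):
            # a 2-channel image is rejected at construction already
            img_from(np.zeros((4, 4, 2)))
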