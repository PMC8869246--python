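"""Core raster operations: I/O, resize, blur, sharpen, morphology."""

import numpy as np
import pytest

from phaseseg import (
    FormatError,
    InputFileError,
    ParameterError,
    binary_close,
    binary_dilate,
    binary_erode,
    binary_open,
    complement,
    full_se,
    gaussian_blur,
    gray_dilate,
    gray_erode,
    read_image,
    resize,
    sharpen,
    write_image,
)
from phaseseg.imaging import check_se, gaussian_kernel_1d, gaussian_sigma_for_kernel

from oracles import ORACLE_SES, dilate_oracle, erode_oracle


class TestReadImage:
    def test_rgb_equal_channels_collapse_to_luminance(self, tmp_path):
        import imageio.v3 as iio

        rgb = np.full((2, 2, 3), 200, dtype=np.uint8)
        iio.imwrite(tmp_path / "a.png", rgb)
        out = read_image(tmp_path / "a.png")
        assert out.shape == (2, 2)
        assert (out == 200).all()

    def test_uint16_rescales_full_scale(self, tmp_path):
        import imageio.v3 as iio

        arr = np.array([[0, 65535], [32768, 65535]], dtype=np.uint16)
        iio.imwrite(tmp_path / "a.tif", arr)
        out = read_image(tmp_path / "a.tif")
        assert out.dtype == np.uint8
        assert out.max() == 255 and out.min() == 0

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(InputFileError, match="nowhere.png"):
            read_image(tmp_path / "nowhere.png")

    def test_corrupt_file_raises_input_error(self, tmp_path):
        p = tmp_path / "bad.png"
        p.write_bytes(b"this is not a png")
        with pytest.raises(InputFileError):
            read_image(p)

    def test_float_tiff_is_unsupported_bit_depth(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "f.tif", np.zeros((3, 3), dtype=np.float32))
        with pytest.raises(FormatError):
            read_image(tmp_path / "f.tif")

    def test_roundtrip_gray_png(self, tmp_path, random_gray):
        img = random_gray(12, 9)
        write_image(tmp_path / "g.png", img)
        assert np.array_equal(read_image(tmp_path / "g.png"), img)


class TestResize:
    def test_default_frame_from_native_camera_size(self):
        img = np.zeros((1040, 1392), dtype=np.uint8)
        out = resize(img, 800, 600)
        assert out.shape == (600, 800)

    def test_resize_to_own_size_is_identity(self, random_gray):
        img = random_gray(20, 30)
        assert np.array_equal(resize(img, 30, 20), img)

    @pytest.mark.parametrize("target", [(10, 7), (120, 90)])
    def test_constant_image_stays_constant(self, target):
        img = np.full((40, 60), 77, dtype=np.uint8)
        out = resize(img, *target)
        assert out.shape == (target[1], target[0])
        assert (out == 77).all()

    def test_nonpositive_target_rejected(self, random_gray):
        with pytest.raises(ParameterError):
            resize(random_gray(), 0, 10)


class TestGaussianBlur:
    def test_kernel_weights_sum_to_one(self):
        for k in (1, 3, 5, 9, 49):
            assert gaussian_kernel_1d(k).sum() == pytest.approx(1.0, abs=1e-9)
            assert (gaussian_kernel_1d(k) >= 0).all()

    def test_constant_image_is_fixed_point(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        assert np.array_equal(gaussian_blur(img, 3), img)

    def test_single_impulse_center_matches_direct_kernel_evaluation(self):
        # independent evaluation of the normalized kernel at the default sigma
        sigma = 0.3 * ((3 - 1) / 2 - 1) + 0.8
        g = np.exp(-np.array([-1.0, 0.0, 1.0]) ** 2 / (2 * sigma**2))
        g /= g.sum()
        expected_center = round(255 * g[1] * g[1])

        img = np.zeros((7, 7), dtype=np.uint8)
        img[3, 3] = 255
        out = gaussian_blur(img, 3)
        assert out[3, 3] == expected_center

    def test_large_kernel_reduces_variance(self, random_gray):
        img = random_gray(64, 64)
        out = gaussian_blur(img, 49)
        assert out.astype(float).var() < img.astype(float).var()

    def test_even_kernel_rejected(self, random_gray):
        with pytest.raises(ParameterError):
            gaussian_blur(random_gray(), 4)

    def test_sigma_convention(self):
        assert gaussian_sigma_for_kernel(3) == pytest.approx(0.8)
        assert gaussian_sigma_for_kernel(7) == pytest.approx(1.4)


class TestSharpen:
    def test_constant_image_unchanged(self):
        img = np.full((6, 6), 128, dtype=np.uint8)
        assert np.array_equal(sharpen(img), img)

    def test_impulse_saturates_center_and_clamps_neighbors(self):
        img = np.zeros((7, 7), dtype=np.uint8)
        img[3, 3] = 100
        out = sharpen(img)
        assert out[3, 3] == 255  # 5 * 100 clamps at 255
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            assert out[3 + di, 3 + dj] == 0  # -100 clamps at 0

    def test_all_white_is_fixed_point(self):
        img = np.full((5, 5), 255, dtype=np.uint8)
        assert np.array_equal(sharpen(img), img)


class TestStructuringElement:
    def test_even_side_rejected(self):
        with pytest.raises(ParameterError):
            check_se(np.ones((2, 3), bool))

    def test_empty_se_rejected(self):
        with pytest.raises(ParameterError):
            check_se(np.zeros((3, 3), bool))


class TestGrayMorphology:
    def test_dilate_spreads_maximum_over_full_window(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        img[1, 1] = 9
        expected = dilate_oracle(img, np.ones((3, 3), bool))
        out = gray_dilate(img, full_se(3))
        assert np.array_equal(out, expected)
        assert (out == 9).all()

    def test_erode_spreads_minimum(self):
        img = np.full((3, 3), 9, dtype=np.uint8)
        img[1, 1] = 0
        out = gray_erode(img, full_se(3))
        assert np.array_equal(out, erode_oracle(img, np.ones((3, 3), bool)))
        assert (out == 0).all()

    def test_constant_image_fixed_under_both(self):
        img = np.full((5, 5), 42, dtype=np.uint8)
        assert np.array_equal(gray_dilate(img), img)
        assert np.array_equal(gray_erode(img), img)

    def test_singleton_se_is_identity(self, random_gray):
        img = random_gray()
        se = np.ones((1, 1), bool)
        assert np.array_equal(gray_dilate(img, se), img)
        assert np.array_equal(gray_erode(img, se), img)

    def test_extensivity_sandwich(self, random_gray):
        for _ in range(20):
            img = random_gray()
            for se in ORACLE_SES:
                assert (gray_erode(img, se) <= img).all()
                assert (img <= gray_dilate(img, se)).all()

    @pytest.mark.parametrize("se_idx", range(len(ORACLE_SES)))
    def test_matches_window_scan_oracle(self, random_gray, se_idx):
        se = ORACLE_SES[se_idx]
        for _ in range(10):
            img = random_gray()
            assert np.array_equal(gray_dilate(img, se), dilate_oracle(img, se))
            assert np.array_equal(gray_erode(img, se), erode_oracle(img, se))


class TestBinaryMorphology:
    def test_dilate_single_pixel_grows_full_block(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 255
        out = binary_dilate(m, full_se(3))
        assert np.array_equal(out, dilate_oracle(m, np.ones((3, 3), bool)))
        assert (out[1:4, 1:4] == 255).all() and out.sum() == 9 * 255

    def test_erode_block_leaves_center(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[2:5, 2:5] = 255
        out = binary_erode(m, full_se(3))
        assert out[3, 3] == 255
        assert (out == 255).sum() == 1

    def test_all_zero_and_all_one_fixed_points(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        o = np.full((4, 4), 255, dtype=np.uint8)
        assert np.array_equal(binary_dilate(z), z)
        assert np.array_equal(binary_erode(o), o)

    def test_de_morgan_duality_for_symmetric_se(self, random_mask):
        for se in (full_se(3), full_se(5), full_se(1, 3)):
            for _ in range(10):
                m = random_mask()
                lhs = binary_erode(m, se)
                rhs = complement(binary_dilate(complement(m), se))
                assert np.array_equal(lhs, rhs)

    def test_open_removes_isolated_pixel(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[3, 3] = 255
        assert (binary_open(m, full_se(3)) == 0).all()

    def test_close_fills_one_pixel_hole(self):
        m = np.full((9, 9), 0, dtype=np.uint8)
        m[2:7, 2:7] = 255
        m[4, 4] = 0
        out = binary_close(m, full_se(3))
        assert out[4, 4] == 255
        assert (out[2:7, 2:7] == 255).all()

    @pytest.mark.parametrize("op", [binary_open, binary_close])
    def test_idempotence(self, random_mask, op):
        for _ in range(15):
            m = random_mask()
            once = op(m, full_se(3))
            assert np.array_equal(op(once, full_se(3)), once)

    def test_rejects_non_binary_input(self, random_gray):
        with pytest.raises(ParameterError):
            binary_dilate(np.full((3, 3), 7, dtype=np.uint8))
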