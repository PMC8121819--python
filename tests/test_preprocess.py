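import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from livedead import (
    MicrographFrame,
    PreprocessParams,
    disk_element,
    gamma_adjust,
    open_by_reconstruction,
    preprocess_frame,
    rolling_ball_subtract,
)
from oracles import brute_disk, brute_open_by_reconstruction

u8_images = hnp.arrays(
    dtype=np.uint8,
    shape=st.tuples(st.integers(4, 12), st.integers(4, 12)),
    elements=st.integers(0, 255),
)


class TestDiskElement:
    def test_radius_one_is_plus_shape(self):
        el = disk_element(1)
        assert el.shape == (3, 3)
        assert el.sum() == 5
        assert not el[0, 0] and el[1, 1]

    def test_radius_three_center_row_full(self):
        el = disk_element(3)
        assert el.shape == (7, 7)
        assert el[3, :].all()

    @pytest.mark.parametrize("radius", [1, 2, 3, 5])
    def test_matches_definition_and_symmetry(self, radius):
        el = disk_element(radius)
        np.testing.assert_array_equal(el, brute_disk(radius))
        np.testing.assert_array_equal(el, np.rot90(el))
        np.testing.assert_array_equal(el, np.fliplr(el))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            disk_element(0)


class TestOpenByReconstruction:
    def test_constant_image_is_fixed_point(self, default_params):
        img = np.full((16, 16), 37, dtype=np.uint8)
        np.testing.assert_array_equal(open_by_reconstruction(img, default_params), img)

    def test_isolated_pixel_removed(self, default_params):
        img = np.zeros((20, 20), dtype=np.uint8)
        img[10, 10] = 200
        assert open_by_reconstruction(img, default_params).max() == 0

    def test_large_object_shape_preserved(self, default_params):
        img = np.zeros((40, 40), dtype=np.uint8)
        img[10:30, 10:30] = 150  # block much larger than the disk
        out = open_by_reconstruction(img, default_params)
        np.testing.assert_array_equal(out, img)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("final_dilation", [True, False])
    def test_matches_bruteforce_oracle(self, seed, final_dilation):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        params = PreprocessParams(disk_radius=1, apply_final_dilation=final_dilation)
        expected = brute_open_by_reconstruction(img, 1, final_dilation)
        np.testing.assert_array_equal(
            open_by_reconstruction(img, params).astype(float), expected
        )

    @settings(max_examples=30, deadline=None)
    @given(img=u8_images)
    def test_anti_extensive(self, img):
        out = open_by_reconstruction(img, PreprocessParams(disk_radius=1))
        assert (out <= img).all()

    @settings(max_examples=20, deadline=None)
    @given(img=u8_images)
    def test_core_is_idempotent_without_final_dilation(self, img):
        params = PreprocessParams(disk_radius=1, apply_final_dilation=False)
        once = open_by_reconstruction(img, params)
        twice = open_by_reconstruction(once, params)
        np.testing.assert_array_equal(once, twice)


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        img = np.full((32, 32), 40, dtype=np.uint8)
        assert rolling_ball_subtract(img, 10).max() == 0

    def test_small_bright_disk_preserved(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        yy, xx = np.mgrid[:64, :64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 5 ** 2
        img[disk] = 180
        out = rolling_ball_subtract(img, 50)
        assert out[32, 32] >= 0.9 * 180
        assert out[~disk].max() <= 5

    def test_output_bounded_by_input(self, rng):
        img = rng.integers(0, 256, (48, 48), dtype=np.uint8)
        out = rolling_ball_subtract(img, 20)
        assert (out <= img).all()
        assert (out >= 0).all()

    def test_ramp_plus_spots_recovered(self):
        # smooth background (linear ramp) removed; spot heights recovered
        yy, xx = np.mgrid[:64, :64]
        ramp = (xx * 60) // 63
        img = ramp.astype(np.int64)
        spots = [(16, 16), (40, 48)]
        for (cy, cx) in spots:
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= 3 ** 2
            img[blob] += 120
        img = np.clip(img, 0, 255).astype(np.uint8)
        out = rolling_ball_subtract(img, 50)
        for (cy, cx) in spots:
            assert abs(int(out[cy, cx]) - 120) <= 12  # within 10%
        far = out[(np.abs(yy - 16) > 8) & (np.abs(yy - 40) > 8)]
        assert np.median(far) <= 5

    @pytest.mark.parametrize("seed", range(3))
    def test_background_matches_grey_opening_oracle(self, seed):
        from livedead.preprocess import rolling_ball_background
        from oracles import brute_rolling_ball_background
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (48, 48), dtype=np.uint8)
        bg = rolling_ball_background(img, 15)
        expected = brute_rolling_ball_background(img, 15)
        np.testing.assert_allclose(bg, expected, atol=1e-9)

    def test_oversized_ball_warns_and_uses_minimum(self):
        img = np.full((16, 16), 7, dtype=np.uint8)
        img[3, 3] = 90
        with pytest.warns(UserWarning, match="global minimum"):
            out = rolling_ball_subtract(img, 100)
        assert out[3, 3] == 83
        assert out[0, 0] == 0


class TestGammaAdjust:
    def test_fixed_points_and_identity(self):
        img = np.array([[0, 255]], dtype=np.uint8)
        for conv in ("brighten_faint", "imagej_power"):
            out = gamma_adjust(img, 1.5, conv, 255)
            assert out[0, 0] == 0 and out[0, 1] == 255
        ramp = np.arange(256, dtype=np.uint8).reshape(16, 16)
        np.testing.assert_array_equal(gamma_adjust(ramp, 1.0, "brighten_faint", 255), ramp)

    def test_brighten_faint_value(self):
        # independent direct evaluation of 255*(64/255)^(2/3)
        expected = round(255.0 * math.pow(64.0 / 255.0, 2.0 / 3.0))
        out = gamma_adjust(np.array([[64]], dtype=np.uint8), 1.5, "brighten_faint", 255)
        assert out[0, 0] == expected

    def test_conventions_move_in_opposite_directions(self):
        mid = np.array([[64]], dtype=np.uint8)
        up = gamma_adjust(mid, 1.5, "brighten_faint", 255)[0, 0]
        down = gamma_adjust(mid, 1.5, "imagej_power", 255)[0, 0]
        assert up > 64 > down

    @settings(max_examples=30, deadline=None)
    @given(img=u8_images, gamma=st.floats(0.2, 5.0))
    def test_monotone(self, img, gamma):
        out = gamma_adjust(img, gamma, "brighten_faint", 255)
        order = np.argsort(img, axis=None)
        assert (np.diff(out.ravel()[order].astype(int)) >= 0).all()

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            gamma_adjust(np.zeros((2, 2), dtype=np.uint8), 0.0)


class TestPreprocessFrame:
    def test_all_zero_frame_unchanged(self, small_params):
        z = np.zeros((32, 32), dtype=np.uint8)
        frame = MicrographFrame(green=z, red=z.copy())
        out = preprocess_frame(frame, small_params)
        assert out.green.max() == 0 and out.red.max() == 0

    def test_uniform_red_haze_removed_green_stays_flat(self, small_params):
        green = np.full((32, 32), 60, dtype=np.uint8)
        red = np.full((32, 32), 30, dtype=np.uint8)
        frame = MicrographFrame(green=green, red=red)
        out = preprocess_frame(frame, small_params)
        assert out.red.max() == 0  # haze is pure background
        assert len(np.unique(out.green)) == 1  # flat stays flat

    def test_bright_cells_survive_composition(self, small_params):
        g = np.zeros((64, 64), dtype=np.uint8)
        r = np.zeros((64, 64), dtype=np.uint8)
        yy, xx = np.mgrid[:64, :64]
        g[(yy - 20) ** 2 + (xx - 20) ** 2 <= 25] = 200
        r[(yy - 44) ** 2 + (xx - 44) ** 2 <= 25] = 200
        frame = MicrographFrame(green=g, red=r)
        out = preprocess_frame(frame, small_params)
        assert out.green[20, 20] >= 100
        assert out.red[44, 44] >= 100

    def test_shape_and_bit_depth_preserved(self, rng, small_params):
        frame = MicrographFrame(
            green=rng.integers(0, 65536, (20, 24), dtype=np.uint16),
            red=rng.integers(0, 65536, (20, 24), dtype=np.uint16),
            bit_depth=16,
        )
        out = preprocess_frame(frame, small_params)
        assert out.shape == (20, 24)
        assert out.bit_depth == 16
        assert out.green.dtype == np.uint16
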