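"""Unit and property tests for the sliding-window first-order feature maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcradiomics.io import ADCImage, ROIMask
from adcradiomics.localmaps import (
    STAT_NAMES,
    compute_all_local_maps,
    compute_local_map,
    first_order_stat,
)

from .oracles import naive_local_map, oracle_stat


class TestFirstOrderStat:
    def test_constant_sample_conventions(self):
        x = [5.0, 5.0, 5.0, 5.0]
        assert first_order_stat(x, "mean") == 5
        assert first_order_stat(x, "std") == 0
        assert first_order_stat(x, "cv") == 0
        assert first_order_stat(x, "entropy") == 0
        assert first_order_stat(x, "uniformity") == 1
        assert first_order_stat(x, "iqr") == 0
        assert first_order_stat(x, "mad") == 0
        assert first_order_stat(x, "skewness") == 0
        assert first_order_stat(x, "kurtosis") == 3  # Pearson, non-excess

    def test_simple_sample_against_direct_formulas(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert first_order_stat(x, "mean") == 2.5
        assert first_order_stat(x, "median") == 2.5
        for stat in ("std", "skewness", "kurtosis", "iqr", "mad", "cv"):
            assert first_order_stat(x, stat) == pytest.approx(
                oracle_stat(x, stat), rel=1e-12
            )

    def test_entropy_of_two_equal_mass_bins_is_one_bit(self):
        # half the sample in the lowest bin, half in the highest
        x = [0.0] * 8 + [1.0] * 8
        assert first_order_stat(x, "entropy") == pytest.approx(1.0)
        assert first_order_stat(x, "uniformity") == pytest.approx(0.5)

    def test_zero_mean_cv_convention(self):
        assert first_order_stat([-1.0, 1.0, -2.0, 2.0], "cv") == 0.0

    def test_rejects_tiny_or_bad_input(self):
        with pytest.raises(ValueError):
            first_order_stat([1.0], "mean")
        with pytest.raises(ValueError):
            first_order_stat([1.0, np.inf], "mean")
        with pytest.raises(ValueError):
            first_order_stat([1.0, 2.0], "nope")

    @given(
        data=st.lists(
            st.floats(min_value=0, max_value=2000, allow_nan=False), min_size=2, max_size=40
        ),
        # histogram stats are covered by the naive-map oracle test, where
        # continuous inputs avoid bin-edge coincidences
        stat=st.sampled_from([s for s in STAT_NAMES if s not in ("entropy", "uniformity")]),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_direct_formula_oracle(self, data, stat):
        got = first_order_stat(data, stat)
        want = oracle_stat(data, stat)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


class TestLocalMaps:
    def test_constant_image_maps(self, flat_image):
        img, gland = flat_image
        maps = compute_all_local_maps(img, gland)
        d = maps.defined_mask
        assert d.any()
        assert np.allclose(maps["mean"][d], 1000.0)
        assert np.allclose(maps["std"][d], 0.0)
        assert np.allclose(maps["uniformity"][d], 1.0)
        assert np.allclose(maps["entropy"][d], 0.0)
        assert np.allclose(maps["kurtosis"][d], 3.0)

    def test_exactly_ten_named_maps_sharing_a_defined_mask(self, random_image):
        img, gland = random_image
        maps = compute_all_local_maps(img, gland)
        assert set(maps.maps) == set(STAT_NAMES)
        assert len(maps.maps) == 10
        for name in STAT_NAMES:
            assert np.array_equal(np.isfinite(maps[name]), maps.defined_mask)

    def test_single_stat_equals_full_computation(self, random_image):
        img, gland = random_image
        maps = compute_all_local_maps(img, gland)
        grid = compute_local_map(img, gland, "iqr")
        assert np.array_equal(
            np.nan_to_num(grid, nan=-1), np.nan_to_num(maps["iqr"], nan=-1)
        )

    def test_single_bright_pixel_window_mean(self):
        pixels = np.full((15, 15), 100.0)
        pixels[7, 7] = 1000.0
        img = ADCImage(pixels, (1, 1))
        gland = ROIMask(np.ones((15, 15), bool), role="gland")
        mean_map = compute_local_map(img, gland, "mean", window_size=9)
        assert mean_map[7, 7] == pytest.approx((80 * 100 + 1000) / 81)

    def test_support_rule_excludes_starved_windows(self):
        pixels = np.full((20, 20), 500.0)
        gland = np.zeros((20, 20), bool)
        gland[0:2, 0:5] = True  # 10 gland pixels: every 9x9 window has < 50% support
        maps = compute_all_local_maps(
            ADCImage(pixels, (1, 1)), ROIMask(gland, role="gland")
        )
        assert not maps.defined_mask.any()

    @pytest.mark.parametrize("stat", STAT_NAMES)
    def test_equivalence_with_naive_double_loop(self, random_image, stat):
        img, gland = random_image
        got = compute_local_map(img, gland, stat)
        want = naive_local_map(img.pixels, gland.mask, stat, 9)
        assert np.array_equal(np.isnan(got), np.isnan(want))
        sel = ~np.isnan(want)
        np.testing.assert_allclose(got[sel], want[sel], rtol=1e-9, atol=1e-9)

    def test_shift_invariance_and_scale_covariance(self, random_image):
        img, gland = random_image
        base = compute_all_local_maps(img, gland)
        shifted = compute_all_local_maps(
            ADCImage(img.pixels + 250.0, img.pixel_spacing), gland
        )
        scaled = compute_all_local_maps(
            ADCImage(img.pixels * 3.0, img.pixel_spacing), gland
        )
        d = base.defined_mask
        for stat in ("std", "iqr", "mad", "entropy", "uniformity", "skewness", "kurtosis"):
            np.testing.assert_allclose(
                shifted[stat][d], base[stat][d], rtol=1e-9, atol=1e-9
            )
        for stat in ("mean", "median", "std", "iqr", "mad"):
            np.testing.assert_allclose(
                scaled[stat][d], 3.0 * base[stat][d], rtol=1e-9, atol=1e-9
            )

    def test_rejects_even_or_oversized_window(self, random_image):
        img, gland = random_image
        with pytest.raises(ValueError):
            compute_all_local_maps(img, gland, window_size=8)
        with pytest.raises(ValueError):
            compute_all_local_maps(img, gland, window_size=21)
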