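"""Unit and property tests of the image-conditioning primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sphereq.preprocessing import (
    PreprocessParams,
    invert,
    label_components,
    median_filter,
    morphological_clean,
    subtract_background_rolling,
    threshold_window,
    to_8bit,
    watershed_split,
)

from conftest import canonical_labels, disk_bool, flood_fill_components, make_image

uint8_images = hnp.arrays(
    np.uint8, hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=24)
)


class TestTo8Bit:
    @pytest.mark.parametrize(
        "value16, expected",
        [(65535, 255), (0, 0), (32768, 128)],  # round(32768/65535*255) = 128
    )
    def test_linear_endpoint_mapping(self, value16, expected):
        img = make_image(np.full((4, 4), value16), dtype_max=65535)
        assert (to_8bit(img).pixels == expected).all()

    def test_identity_on_8bit(self):
        img = make_image(np.arange(256).reshape(16, 16) % 256)
        out = to_8bit(img)
        assert out is img

    def test_idempotent(self):
        img = make_image(np.full((3, 3), 40000), dtype_max=65535)
        once = to_8bit(img)
        assert (to_8bit(once).pixels == once.pixels).all()


class TestInvert:
    def test_zero_maps_to_255_and_13_to_242(self):
        img = make_image([[0, 13], [255, 100]])
        assert invert(img).pixels.tolist() == [[255, 242], [0, 155]]

    @given(uint8_images)
    def test_involution(self, arr):
        img = make_image(arr)
        assert (invert(invert(img)).pixels == arr).all()

    def test_rejects_16bit(self):
        with pytest.raises(ValueError, match="8-bit"):
            invert(make_image(np.zeros((2, 2)), dtype_max=65535))


class TestRollingBackground:
    def test_flat_background_fully_removed(self):
        img = make_image(np.full((80, 80), 40))
        assert (subtract_background_rolling(img, 30).pixels == 0).all()

    def test_small_bright_object_preserved(self):
        arr = np.zeros((100, 100), np.uint8)
        arr[50:53, 50:53] = 200
        out = subtract_background_rolling(make_image(arr), 30).pixels
        assert (out[50:53, 50:53] == 200).all()
        assert out.sum() == 9 * 200

    @given(uint8_images)
    def test_anti_extensive(self, arr):
        out = subtract_background_rolling(make_image(arr), 3).pixels
        assert (out <= arr).all()

    def test_radius_validated(self):
        with pytest.raises(ValueError):
            subtract_background_rolling(make_image(np.zeros((4, 4))), 0)


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = make_image(np.full((10, 10), 77))
        assert (median_filter(img, 1).pixels == 77).all()

    def test_hot_pixel_removed(self):
        arr = np.zeros((9, 9), np.uint8)
        arr[4, 4] = 255
        assert median_filter(make_image(arr), 1).pixels.sum() == 0

    def test_matches_bruteforce_disk_median(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        out = median_filter(make_image(arr), 1).pixels
        # brute-force: median over the radius-1 disk (plus-shaped, 5 px),
        # borders replicated
        pad = np.pad(arr, 1, mode="edge")
        for r in range(5):
            for c in range(5):
                neigh = [
                    pad[r + 1, c + 1], pad[r, c + 1], pad[r + 2, c + 1],
                    pad[r + 1, c], pad[r + 1, c + 2],
                ]
                assert out[r, c] == int(np.median(neigh)), (r, c)


class TestThresholdWindow:
    def test_inclusive_bounds(self):
        img = make_image([[0, 13, 14]])
        assert threshold_window(img, 0, 13).tolist() == [[True, True, False]]

    def test_full_window_covers_image(self):
        img = make_image([[0, 128, 255]])
        assert threshold_window(img, 0, 255).all()

    def test_degenerate_window(self):
        img = make_image([[50, 49]])
        assert threshold_window(img, 50, 50).tolist() == [[True, False]]

    def test_lo_above_hi_rejected(self):
        with pytest.raises(ValueError):
            threshold_window(make_image([[0]]), 10, 5)

    @given(uint8_images, st.integers(0, 254))
    def test_windows_partition_image(self, arr, cut):
        img = make_image(arr)
        lo = threshold_window(img, 0, cut)
        hi = threshold_window(img, cut + 1, 255)
        assert not (lo & hi).any()
        assert (lo | hi).all()


class TestMorphologicalClean:
    def test_closing_fills_small_hole(self):
        mask = disk_bool((150, 150), (75, 75), 60)
        holey = mask.copy()
        holey[73:78, 73:78] = False
        out = morphological_clean(holey, 25)
        assert out[73:78, 73:78].all()

    def test_opening_removes_speck(self):
        mask = np.zeros((100, 100), bool)
        mask[50:53, 50:53] = True
        assert not morphological_clean(mask, 25).any()

    def test_large_disk_area_preserved(self):
        # margins exceed the element radius so border padding cannot distort
        mask = disk_bool((240, 240), (120, 120), 60)
        out = morphological_clean(mask, 25)
        assert abs(out.sum() - mask.sum()) <= 0.02 * mask.sum()


class TestWatershedSplit:
    def test_disjoint_disks_get_two_labels(self):
        mask = disk_bool((100, 200), (50, 50), 20) | disk_bool((100, 200), (50, 150), 20)
        labels = watershed_split(mask, 5)
        assert labels.max() == 2
        assert (labels[mask] > 0).all()

    def test_overlapping_disks_split_at_waist(self):
        mask = disk_bool((100, 120), (50, 40), 20) | disk_bool((100, 120), (50, 70), 20)
        labels = watershed_split(mask, 5)
        assert labels.max() == 2
        assert labels[50, 40] != labels[50, 70] and labels[50, 40] > 0

    def test_empty_mask(self):
        assert watershed_split(np.zeros((10, 10), bool), 5).sum() == 0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) > 0.6
        a = watershed_split(mask, 3)
        b = watershed_split(mask, 3)
        assert (a == b).all()

    def test_every_foreground_pixel_labeled_once(self):
        rng = np.random.default_rng(9)
        mask = rng.random((64, 64)) > 0.5
        labels = watershed_split(mask, 3)
        assert ((labels > 0) == mask).all()

    def test_singleton_seeds_reduce_to_connected_components(self):
        # well-separated compact blobs: one seed each, so watershed labeling
        # must coincide with plain connected components
        mask = np.zeros((60, 60), bool)
        for ctr in [(10, 10), (10, 45), (45, 25)]:
            mask |= disk_bool((60, 60), ctr, 5)
        ws = canonical_labels(watershed_split(mask, 5))
        cc = canonical_labels(label_components(mask))
        assert (ws == cc).all()


class TestLabelComponents:
    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            mask = rng.random((32, 32)) > 0.7
            got = canonical_labels(label_components(mask))
            want = canonical_labels(flood_fill_components(mask))
            assert (got == want).all()


def test_params_validation():
    with pytest.raises(ValueError):
        PreprocessParams(threshold_lo=20, threshold_hi=10)
    with pytest.raises(ValueError):
        PreprocessParams(threshold_hi=300)
    with pytest.raises(ValueError):
        PreprocessParams(median_radius=0)
    with pytest.raises(ValueError):
        PreprocessParams(window_selects="both")
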