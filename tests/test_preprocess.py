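"""Unit and property tests for the segmentation/filtering pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from rootmorph import preprocess as pp
from rootmorph.errors import EmptyInputError, ParameterError, PipelineError

# ---------------------------------------------------------------------------
# independent oracles


def isodata_oracle(pixels: np.ndarray, t0: int) -> int:
    """Independently coded ISODATA threshold working on raw pixel values."""
    t = int(t0)
    for _ in range(1000):
        low = pixels[pixels <= t]
        high = pixels[pixels > t]
        if len(low) == 0 or len(high) == 0:
            return t
        t_next = int(np.floor(0.5 * (low.mean() + high.mean()) + 0.5))
        if t_next == t:
            return t
        t = t_next
    raise AssertionError("oracle did not converge")


def median_oracle(img: np.ndarray, wh: int, ww: int) -> np.ndarray:
    """Per-pixel sort-the-window median; truncated windows at the border,
    lower median on even counts."""
    h, w = img.shape
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            win = img[max(0, r - wh // 2) : r + wh // 2 + 1,
                      max(0, c - ww // 2) : c + ww // 2 + 1]
            flat = np.sort(win, axis=None)
            out[r, c] = flat[(flat.size - 1) // 2]
    return out


def minkowski_dilate_oracle(a: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Direct set-translation enumeration of the Minkowski sum."""
    h, w = a.shape
    orow, ocol = se.shape[0] // 2, se.shape[1] // 2
    out = np.zeros_like(a, dtype=bool)
    for (r, c) in zip(*np.nonzero(a)):
        for (br, bc) in zip(*np.nonzero(se)):
            z = (r + br - orow, c + bc - ocol)
            if 0 <= z[0] < h and 0 <= z[1] < w:
                out[z] = True
    return out


def erode_oracle(a: np.ndarray, se: np.ndarray) -> np.ndarray:
    """z is kept iff every cell of the translated element lies in A
    (out-of-image counts as background)."""
    h, w = a.shape
    orow, ocol = se.shape[0] // 2, se.shape[1] // 2
    out = np.zeros_like(a, dtype=bool)
    for r in range(h):
        for c in range(w):
            ok = True
            for (br, bc) in zip(*np.nonzero(se)):
                z = (r + br - orow, c + bc - ocol)
                if not (0 <= z[0] < h and 0 <= z[1] < w) or not a[z]:
                    ok = False
                    break
            out[r, c] = ok
    return out


# ---------------------------------------------------------------------------
# cropping


class TestCrop:
    def test_identity_crop(self):
        img = np.arange(300, dtype=np.uint8).reshape(10, 10, 3)
        out = pp.crop_to_plate(img, (0, 10, 0, 10))
        assert np.array_equal(out, img)

    def test_subrectangle(self):
        img = np.random.default_rng(0).integers(0, 256, (10, 10, 3), dtype=np.uint8)
        out = pp.crop_to_plate(img, (2, 6, 3, 8))
        assert out.shape == (4, 5, 3)
        assert np.array_equal(out[0, 0], img[2, 3])

    @pytest.mark.parametrize("rect", [(-1, 5, 0, 5), (0, 11, 0, 5), (5, 5, 0, 5), (0, 5, 3, 2)])
    def test_out_of_bounds(self, rect):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ParameterError):
            pp.crop_to_plate(img, rect)

    def test_crop_keeps_all_root_pixels(self, suite):
        """Cropping to a rectangle containing the root keeps every
        ground-truth root pixel (at shifted coordinates)."""
        spec, img, gt = suite["y_branch"]
        rows, cols = gt.root_pixel_set[:, 0], gt.root_pixel_set[:, 1]
        top, left = rows.min() - 5, cols.min() - 5
        rect = (top, rows.max() + 6, left, cols.max() + 6)
        out = pp.crop_to_plate(img, rect)
        root_color = np.asarray(spec.root_color, dtype=np.uint8)
        assert np.all(out[rows - top, cols - left] == root_color)


# ---------------------------------------------------------------------------
# grayscale


class TestToGray:
    @pytest.mark.parametrize(
        "rgb,mode,expected",
        [
            ((255, 255, 255), "weighted", 255),
            ((0, 0, 0), "weighted", 0),
            ((0, 0, 0), "blue_channel", 0),
            ((255, 0, 0), "weighted", 76),  # 255*0.299 = 76.245
            ((10, 20, 200), "blue_channel", 200),
        ],
    )
    def test_single_pixel(self, rgb, mode, expected):
        img = np.full((2, 2, 3), rgb, dtype=np.uint8)
        assert np.all(pp.to_gray(img, mode) == expected)

    def test_bad_shape(self):
        with pytest.raises(ParameterError):
            pp.to_gray(np.zeros((4, 4), dtype=np.uint8))


# ---------------------------------------------------------------------------
# histogram


class TestHistogram:
    def test_constant_image(self):
        h = pp.compute_histogram(np.full((2, 2), 7, dtype=np.uint8))
        assert h[7] == 4 and h.sum() == 4

    def test_small_mixed(self):
        img = np.array([[0, 0, 255]], dtype=np.uint8)
        h = pp.compute_histogram(img)
        assert h[0] == 2 and h[255] == 1

    def test_random_matches_tally(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        h = pp.compute_histogram(img)
        tally = np.zeros(256, dtype=int)
        for v in img.ravel():
            tally[v] += 1
        assert np.array_equal(h, tally)

    @given(hnp.arrays(np.uint8, hnp.array_shapes(min_dims=2, max_dims=2, max_side=16)))
    @settings(deadline=None, max_examples=50)
    def test_conservation(self, img):
        assert pp.compute_histogram(img).sum() == img.size


# ---------------------------------------------------------------------------
# thresholds


def gaussian_counts(center, sigma, mass):
    k = np.arange(256)
    w = np.exp(-0.5 * ((k - center) / sigma) ** 2)
    return np.round(mass * w / w.sum()).astype(int)


class TestValleyThreshold:
    def test_bimodal_with_unique_valley(self):
        """Two overlapping modes at 40 and 200: the threshold lands at the
        density minimum of the continuous mixture (≈ 111, found by bounded
        minimization of the two-Gaussian pdf)."""
        counts = gaussian_counts(40, 25, 100000) + gaussian_counts(200, 35, 100000)
        res = pp.valley_threshold(counts)
        assert res is not None and res.method == "valley"
        assert abs(res.threshold - 111) <= 3

    def test_unimodal_returns_none(self):
        assert pp.valley_threshold(gaussian_counts(128, 20, 10000)) is None

    def test_flat_zero_valley_not_unique(self):
        counts = np.zeros(256, dtype=int)
        counts[50] = 100
        counts[180] = 100
        assert pp.valley_threshold(counts) is None

    def test_all_zero_histogram(self):
        with pytest.raises(EmptyInputError):
            pp.valley_threshold(np.zeros(256, dtype=int))


class TestIterativeThreshold:
    def test_two_spike_fixed_point(self):
        counts = np.zeros(256, dtype=int)
        counts[0] = counts[255] = 1000
        res = pp.iterative_threshold(counts, t0=128)
        assert res.threshold == 128  # round-half-up of 127.5
        assert res.method == "iterative"

    def test_degenerate_single_level(self):
        counts = np.zeros(256, dtype=int)
        counts[100] = 50
        res = pp.iterative_threshold(counts)
        assert res.threshold == 100 and res.iterations == 0

    def test_all_zero(self):
        with pytest.raises(EmptyInputError):
            pp.iterative_threshold(np.zeros(256, dtype=int))

    def test_terminates_within_cap(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.integers(0, 100, 256)
            res = pp.iterative_threshold(counts)
            assert res.iterations <= 256

    def test_t0_invariance_on_two_spikes(self):
        """On a two-spike histogram the fixed point does not depend on any
        starting threshold strictly between the two class means."""
        counts = np.zeros(256, dtype=int)
        counts[30] = 500
        counts[220] = 1500
        results = {pp.iterative_threshold(counts, t0=t0).threshold for t0 in range(31, 220)}
        assert len(results) == 1

    def test_matches_pixel_oracle_on_two_class_images(self):
        """Fixed point agrees with an independently coded pixel-space
        ISODATA on random two-class images (class means ~30 and ~220)."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_dark = rng.integers(50, 500)
            pixels = np.concatenate([
                np.clip(rng.normal(30, 8, n_dark), 0, 255),
                np.clip(rng.normal(220, 10, 1024 - n_dark), 0, 255),
            ]).astype(np.uint8)
            counts = np.bincount(pixels, minlength=256)
            ours = pp.iterative_threshold(counts, t0=128).threshold
            assert abs(ours - isodata_oracle(pixels, 128)) <= 1


class TestApplyThreshold:
    def test_strict_inequality_bright(self):
        img = np.full((3, 3), 128, dtype=np.uint8)
        assert pp.apply_threshold(img, 127, "bright_foreground").all()
        assert not pp.apply_threshold(img, 128, "bright_foreground").any()

    def test_dark_foreground_inverts(self):
        img = np.array([[10, 200]], dtype=np.uint8)
        mask = pp.apply_threshold(img, 100, "dark_foreground")
        assert mask.tolist() == [[True, False]]

    def test_bad_threshold(self):
        with pytest.raises(ParameterError):
            pp.apply_threshold(np.zeros((2, 2), dtype=np.uint8), 300)


# ---------------------------------------------------------------------------
# median filter


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((8, 8), 42, dtype=np.uint8)
        assert np.array_equal(pp.median_filter(img, (3, 3)), img)

    def test_isolated_impulse_removed(self):
        img = np.zeros((7, 7), dtype=np.uint8)
        img[3, 3] = 255
        assert pp.median_filter(img, (3, 3)).max() == 0

    def test_window_larger_than_image(self):
        with pytest.raises(ParameterError):
            pp.median_filter(np.zeros((3, 3), dtype=np.uint8), (5, 5))

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            pp.median_filter(np.zeros((8, 8), dtype=np.uint8), (4, 3))

    @pytest.mark.parametrize("window", [(3, 3), (5, 3), (5, 5)])
    def test_matches_bruteforce_oracle(self, window):
        rng = np.random.default_rng(3)
        for _ in range(10):
            img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            assert np.array_equal(
                pp.median_filter(img, window), median_oracle(img, *window)
            )

    def test_binary_mask_roundtrip(self):
        rng = np.random.default_rng(4)
        mask = rng.random((12, 12)) < 0.3
        out = pp.median_filter(mask, (3, 3))
        assert out.dtype == bool


# ---------------------------------------------------------------------------
# morphology


class TestMorphology:
    def test_dilate_single_pixel(self):
        a = np.zeros((7, 7), dtype=bool)
        a[3, 3] = True
        out = pp.dilate(a, pp.box(3))
        assert out.sum() == 9 and out[2:5, 2:5].all()

    def test_dilate_empty(self):
        assert not pp.dilate(np.zeros((5, 5), dtype=bool), pp.box(3)).any()

    def test_erode_single_pixel(self):
        a = np.zeros((7, 7), dtype=bool)
        a[3, 3] = True
        assert not pp.erode(a, pp.box(3)).any()

    def test_erode_solid_block(self):
        a = np.zeros((9, 9), dtype=bool)
        a[2:7, 2:7] = True
        out = pp.erode(a, pp.box(3))
        expected = np.zeros((9, 9), dtype=bool)
        expected[3:6, 3:6] = True
        assert np.array_equal(out, expected)

    def test_matches_set_translation_oracles(self):
        rng = np.random.default_rng(5)
        se = pp.box(3)
        for _ in range(20):
            a = rng.random((16, 16)) < 0.4
            assert np.array_equal(pp.dilate(a, se), minkowski_dilate_oracle(a, se))
            assert np.array_equal(pp.erode(a, se), erode_oracle(a, se))

    @given(hnp.arrays(bool, (16, 16)), st.sampled_from([3, 5]))
    @settings(deadline=None, max_examples=120)
    def test_erosion_dilation_duality(self, a, size):
        """complement(A ⊖ B) == complement(A) ⊕ B̂, bit-exact; the out-of-image
        region is background for A hence foreground for its complement."""
        se = pp.box(size)
        lhs = ~pp.erode(a, se, border_value=0)
        rhs = pp.dilate(~a, pp.reflect_se(se), border_value=1)
        assert np.array_equal(lhs, rhs)

    @given(hnp.arrays(bool, (16, 16)))
    @settings(deadline=None, max_examples=60)
    def test_extensivity_and_idempotence(self, a):
        se = pp.box(3)
        opened = pp.binary_open(a, se)
        closed = pp.binary_close(a, se)
        assert not (opened & ~a).any()  # open is anti-extensive
        assert not (a & ~closed).any()  # close is extensive
        assert np.array_equal(pp.binary_open(opened, se), opened)
        assert np.array_equal(pp.binary_close(closed, se), closed)

    def test_open_removes_speck(self):
        a = np.zeros((7, 7), dtype=bool)
        a[3, 3] = True
        assert not pp.binary_open(a, pp.box(3)).any()

    def test_close_fills_hole(self):
        a = np.ones((9, 9), dtype=bool)
        a[4, 4] = False
        assert pp.binary_close(a, pp.box(3)).all()


# ---------------------------------------------------------------------------
# full pipeline


class TestPipeline:
    def test_blank_plate_gives_empty_mask(self, suite):
        _, img, _ = suite["blank_plate"]
        mask, tres = pp.preprocess_pipeline(img)
        assert not mask.any()

    def test_noise_free_mask_matches_ground_truth_count(self, measured):
        _, gt, mask, _, _ = measured["axial_tube"]
        assert abs(int(mask.sum()) - gt.root_pixel_count) <= 0.01 * gt.root_pixel_count

    def test_deterministic(self, suite):
        _, img, _ = suite["diagonal_tube"]
        m1, t1 = pp.preprocess_pipeline(img)
        m2, t2 = pp.preprocess_pipeline(img)
        assert np.array_equal(m1, m2) and t1 == t2

    def test_stage_identity_attached_on_error(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(PipelineError) as exc:
            pp.preprocess_pipeline(img, pp.PipelineConfig(crop=(0, 20, 0, 20)))
        assert exc.value.stage == "crop"

    def test_valley_method_rejects_unimodal(self):
        img = np.full((20, 20, 3), 200, dtype=np.uint8)
        with pytest.raises(PipelineError):
            pp.preprocess_pipeline(img, pp.PipelineConfig(threshold_method="valley"))
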