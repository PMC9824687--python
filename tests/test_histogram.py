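"""Histogram, equalization, multilevel Otsu and region labelling."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammoprep import (
    BinaryMask,
    GrayImage,
    Histogram,
    Region,
    ThresholdSet,
    compute_histogram,
    equalize_global,
    label_regions,
    otsu_multithreshold,
)


def make_hist(counts):
    counts = np.asarray(counts)
    return Histogram(counts, np.linspace(0, 1, counts.size + 1))


def brute_force_otsu(counts, k):
    """Independent oracle: enumerate every cut placement, exact arithmetic.

    Scores each placement by sum over classes of s_c^2 / w_c (equivalent to
    between-class variance up to constants), using Fractions so ties are
    exact; the lexicographically smallest maximizing cut tuple wins.
    """
    B = len(counts)
    centers = [Fraction(2 * i + 1, 2 * B) for i in range(B)]
    best_score, best_cuts = None, None
    for cuts in combinations(range(1, B), k):
        bounds = (0,) + cuts + (B,)
        score = Fraction(0)
        for a, b in zip(bounds, bounds[1:]):
            w = sum(counts[a:b])
            if w:
                s = sum(counts[i] * centers[i] for i in range(a, b))
                score += s * s / w
        if best_score is None or score > best_score:
            best_score, best_cuts = score, cuts
    return [c / B for c in best_cuts]


class TestComputeHistogram:
    def test_binning_rule(self):
        img = GrayImage(np.array([[0.0, 0.5], [0.5, 1.0]]), "unit")
        h = compute_histogram(img, 2)
        np.testing.assert_array_equal(h.counts, [1, 3])

    def test_constant_image_single_bin(self):
        img = GrayImage(np.full((3, 3), 0.3), "unit")
        h = compute_histogram(img, 10)
        assert h.counts[3] == 9 and h.total == 9

    def test_mask_excludes_pixels(self):
        img = GrayImage(np.array([[0.1, 0.9]]), "unit")
        h = compute_histogram(img, 2, BinaryMask(np.array([[1, 0]])))
        np.testing.assert_array_equal(h.counts, [1, 0])

    def test_empty_mask_error(self):
        img = GrayImage(np.array([[0.1]]), "unit")
        with pytest.raises(ValueError, match="empty region"):
            compute_histogram(img, 2, BinaryMask(np.array([[0]])))

    @given(st.integers(0, 2**32 - 1), st.integers(2, 32))
    @settings(max_examples=30)
    def test_conservation(self, seed, n_bins):
        px = np.random.default_rng(seed).random((6, 7))
        h = compute_histogram(GrayImage(px, "unit"), n_bins)
        assert h.total == 42


class TestEqualizeGlobal:
    def test_constant_maps_to_one(self):
        img = GrayImage(np.full((4, 4), 0.3), "unit")
        assert np.all(equalize_global(img).pixels == 1.0)

    def test_two_value_cdf(self):
        img = GrayImage(np.array([[0.0, 0.0, 1.0, 1.0]]), "unit")
        out = equalize_global(img, 2)
        np.testing.assert_allclose(np.unique(out.pixels), [0.5, 1.0])

    def test_flattens_histogram(self, rng):
        # skewed input: max bin count must not increase under equalization
        px = rng.beta(0.5, 3.0, size=(64, 64))
        img = GrayImage(px, "unit")
        before = compute_histogram(img, 32).counts.max()
        after = compute_histogram(equalize_global(img, 32), 32).counts.max()
        assert after <= before

    def test_monotone(self, rng):
        px = rng.random((16, 16))
        out = equalize_global(GrayImage(px, "unit")).pixels
        order = np.argsort(px.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= 0)

    def test_idempotent_up_to_binning(self, rng):
        B = 64
        img = GrayImage(rng.random((32, 32)), "unit")
        once = equalize_global(img, B)
        twice = equalize_global(once, B)
        assert np.max(np.abs(twice.pixels - once.pixels)) <= 1.0 / B + 1e-12


class TestOtsuMultithreshold:
    def test_tie_breaks_to_smallest_cut(self):
        h = make_hist([4, 0, 0, 0, 0, 0, 0, 4])
        t = otsu_multithreshold(h, 1)
        assert t.values[0] == pytest.approx(1 / 8)

    def test_four_regions_three_thresholds(self, phantom_clean):
        h = compute_histogram(phantom_clean.image, 256)
        t = otsu_multithreshold(h, 3)
        assert t.values.size == 3 and t.n_regions == 4

    def test_degenerate_histogram_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_multithreshold(make_hist([0, 9, 0, 0]), 2)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_exhaustive_oracle(self, k):
        rng = np.random.default_rng(k)
        for _ in range(40):
            counts = rng.integers(0, 30, size=16)
            if np.count_nonzero(counts) < k + 1:
                continue
            got = otsu_multithreshold(make_hist(counts), k).values
            np.testing.assert_allclose(got, brute_force_otsu(counts.tolist(), k))


class TestLabelRegions:
    def test_interval_rule(self):
        img = GrayImage(np.array([[0.2, 0.5, 0.9]]), "unit")
        labels = label_regions(img, ThresholdSet(np.array([0.33, 0.66])))
        np.testing.assert_array_equal(labels, [[0, 1, 2]])

    def test_boundary_goes_up(self):
        img = GrayImage(np.array([[0.33]]), "unit")
        labels = label_regions(img, ThresholdSet(np.array([0.33, 0.66])))
        assert labels[0, 0] == 1

    def test_phantom_tissue_order(self, phantom_clean):
        """Four-region labelling orders tissues background < fatty < dense <
        pathology by mean intensity, matching the phantom's ground truth."""
        img = phantom_clean.image
        h = compute_histogram(img, 256)
        labels = label_regions(img, otsu_multithreshold(h, 3))
        means = [img.pixels[labels == i].mean() for i in range(4)]
        assert np.all(np.diff(means) > 0)
        # background pixels overwhelmingly get the lowest label
        bg = phantom_clean.region_labels == int(Region.BACKGROUND)
        assert (labels[bg] == 0).mean() > 0.99
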