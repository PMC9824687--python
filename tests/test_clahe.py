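"""CLAHE: clip limit, redistribution, transfer functions, interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mammoprep import (
    CLAHE_PRESETS,
    ClaheParams,
    GrayImage,
    Histogram,
    clip_histogram,
    compute_clip_limit,
    denormalize,
    enhance_clahe,
    equalize_global,
    make_transfer,
    normalize_unit,
)


def make_hist(counts):
    counts = np.asarray(counts)
    return Histogram(counts, np.linspace(0, 1, counts.size + 1))


class TestClipLimit:
    @pytest.mark.parametrize(
        "clip,tp,nb,expected",
        [
            (1.0, 4096, 256, 4096),   # no clipping possible
            (0.0, 4096, 256, 16),     # uniform-histogram floor
            (0.01, 4096, 256, 40),    # max(16, floor(40.96))
        ],
    )
    def test_formula(self, clip, tp, nb, expected):
        assert compute_clip_limit(clip, tp, nb) == expected

    def test_at_least_one(self):
        assert compute_clip_limit(0.0, 3, 256) == 1


class TestClipHistogram:
    def test_hand_trace(self):
        out = clip_histogram(make_hist([10, 0, 0, 0]), 4)
        np.testing.assert_array_equal(out.counts, [6, 2, 1, 1])

    def test_below_limit_unchanged(self):
        out = clip_histogram(make_hist([3, 1, 4, 1]), 5)
        np.testing.assert_array_equal(out.counts, [3, 1, 4, 1])

    @given(
        counts=hnp.arrays(np.int64, st.integers(2, 24), elements=st.integers(0, 500)),
        limit=st.integers(1, 200),
    )
    @settings(max_examples=100)
    def test_conservation_exact(self, counts, limit):
        h = make_hist(counts)
        assert clip_histogram(h, limit).total == h.total


class TestMakeTransfer:
    def test_uniform_cdf(self):
        m = make_transfer(make_hist([2, 2]), ClaheParams(), 0.0, 1.0)
        np.testing.assert_allclose(m.levels, [0.5, 1.0])

    def test_all_mass_last_bin_maps_to_top(self):
        m = make_transfer(make_hist([0, 0, 0, 8]), ClaheParams(), 0.0, 1.0)
        assert m.levels[-1] == 1.0

    @pytest.mark.parametrize("dist", ["uniform", "rayleigh", "exponential"])
    def test_monotone(self, dist, rng):
        counts = rng.integers(0, 50, size=64)
        counts[0] += 1
        m = make_transfer(make_hist(counts), ClaheParams(distribution=dist), 0.0, 255.0)
        assert np.all(np.diff(m.levels) >= 0)

    def test_distributions_similar_on_flat_histogram(self):
        """On a flat histogram the three target shapes give nearly the same
        map: at the default alpha the largest pairwise gap is the
        rayleigh-vs-uniform bow of about 0.12 of the output span."""
        flat = make_hist(np.full(64, 16))
        maps = [
            make_transfer(flat, ClaheParams(distribution=d), 0.0, 1.0).levels
            for d in ("uniform", "rayleigh", "exponential")
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.max(np.abs(maps[i] - maps[j])) < 0.15


class TestEnhanceClahe:
    def test_single_tile_no_clip_equals_global_equalization(self, rng):
        """Degenerate configuration reduces CLAHE to global equalization."""
        px = rng.integers(0, 256, size=(64, 64))
        img = GrayImage(px, 8)
        params = ClaheParams(tiles=(1, 1), clip_norm=1.0)
        got = enhance_clahe(img, params)
        expected = denormalize(equalize_global(normalize_unit(img), 256), 8)
        assert np.max(np.abs(got.pixels - expected.pixels)) <= 1

    def test_interior_pixel_bilinear_oracle(self, rng):
        """Each interior pixel is the bilinear blend of its 4 neighbouring
        tile maps, recomputed here independently per pixel."""
        from mammoprep.clahe import _output_range, make_transfer

        px = rng.integers(0, 256, size=(96, 96))
        img = GrayImage(px, 8)
        params = ClaheParams(tiles=(3, 3), clip_norm=0.05)
        got = enhance_clahe(img, params)

        th = tw = 32
        out_lo, out_hi = _output_range(img, params)
        limit = compute_clip_limit(params.clip_norm, th * tw, params.n_bins)
        edges = np.linspace(0, 1, params.n_bins + 1)
        bins = np.clip((px / 255.0 * params.n_bins).astype(int), 0, params.n_bins - 1)

        def tile_map(i, j):
            t = bins[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            counts = np.bincount(t.ravel(), minlength=params.n_bins)
            clipped = clip_histogram(Histogram(counts, edges), limit)
            return make_transfer(clipped, params, out_lo, out_hi).levels

        maps = {(i, j): tile_map(i, j) for i in range(3) for j in range(3)}
        for r, c in [(16, 16), (40, 23), (47, 48), (63, 79), (79, 79), (50, 50)]:
            ry = (r + 0.5) / th - 0.5
            cx = (c + 0.5) / tw - 0.5
            i0, j0 = int(np.floor(ry)), int(np.floor(cx))
            wy, wx = ry - i0, cx - j0
            b = bins[r, c]
            blend = (
                (1 - wy) * (1 - wx) * maps[(i0, j0)][b]
                + (1 - wy) * wx * maps[(i0, j0 + 1)][b]
                + wy * (1 - wx) * maps[(i0 + 1, j0)][b]
                + wy * wx * maps[(i0 + 1, j0 + 1)][b]
            )
            assert got.pixels[r, c] == int(np.floor(blend + 0.5))

    def test_test6_preset_range(self, phantom_clean):
        img8 = denormalize(phantom_clean.image, 8)
        out = enhance_clahe(img8, CLAHE_PRESETS["test6"])
        assert out.depth == 8
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255

    def test_deterministic(self, rng):
        px = rng.integers(0, 256, size=(40, 56))
        img = GrayImage(px, 8)
        a = enhance_clahe(img, CLAHE_PRESETS["test4"])
        b = enhance_clahe(img, CLAHE_PRESETS["test4"])
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_non_divisible_size_padded(self, rng):
        # 50x46 with an 8x8 grid: tiles are 7x6 after ceil, symmetric padding
        px = rng.integers(0, 256, size=(50, 46))
        out = enhance_clahe(GrayImage(px, 8), ClaheParams(tiles=(8, 8)))
        assert out.shape == (50, 46)

    def test_original_range_mode(self, rng):
        px = rng.integers(40, 201, size=(64, 64))
        img = GrayImage(px, 8)
        out = enhance_clahe(img, ClaheParams(range_mode="original"))
        assert out.pixels.min() >= 40 and out.pixels.max() <= 200

    def test_tile_too_large_error(self):
        img = GrayImage(np.zeros((4, 4), dtype=int), 8)
        with pytest.raises(ValueError, match="tile too large"):
            enhance_clahe(img, ClaheParams(tiles=(8, 8)))

    @pytest.mark.parametrize("preset", ["test4", "test5", "test6"])
    def test_enhancement_increases_breast_contrast(self, phantom_clean, preset):
        """Within-breast intensity spread strictly increases for every
        published CLAHE preset on a low-contrast phantom."""
        img = phantom_clean.image
        breast = phantom_clean.silhouette_truth.astype_bool()
        out = enhance_clahe(img, CLAHE_PRESETS[preset])
        assert out.pixels[breast].std() > img.pixels[breast].std()
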