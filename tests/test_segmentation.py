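"""Gaussian thresholding, binarization, candidate mask and object detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from yeastcount import (
    BinaryMask,
    ChannelImage,
    ThresholdParams,
    binarize,
    candidate_mask,
    denoise,
    find_objects,
    gaussian_threshold,
    image_stats,
    otsu_threshold,
)
from yeastcount.pipeline import analyze_frame
from yeastcount.synthetic import SceneSpec, generate_scene

from ._oracles import flood_fill_components


def chan(arr):
    return ChannelImage(np.asarray(arr, dtype=np.uint8), "green")


class TestImageStats:
    @pytest.mark.parametrize(
        "pixels, mu, sigma",
        [
            (np.full((5, 5), 100), 100.0, 0.0),
            ([[0, 255]], 127.5, 127.5),
            ([[10, 10], [20, 20]], 15.0, 5.0),
        ],
    )
    def test_hand_arithmetic(self, pixels, mu, sigma):
        got_mu, got_sigma = image_stats(chan(pixels))
        assert got_mu == pytest.approx(mu)
        assert got_sigma == pytest.approx(sigma)  # population (1/MN) form


class TestGaussianThreshold:
    def test_constant_image_sigma_zero(self):
        t = gaussian_threshold(chan(np.full((4, 4), 100)), ThresholdParams(3, "dark_objects"))
        assert t == 100.0

    def test_clamped_to_zero(self):
        # mu=127.5, sigma=127.5 -> raw T = 127.5 - 3*127.5 = -255 -> 0
        t = gaussian_threshold(chan([[0, 255]]), ThresholdParams(3, "dark_objects"))
        assert t == 0.0

    def test_default_alpha_is_three(self):
        assert ThresholdParams().alpha == 3.0

    def test_bright_polarity_mirrors(self):
        img = chan([[10, 10], [20, 20]])  # mu 15, sigma 5
        assert gaussian_threshold(img, ThresholdParams(2, "bright_objects")) == 25.0
        assert gaussian_threshold(img, ThresholdParams(2, "dark_objects")) == 5.0

    @given(
        hnp.arrays(np.uint8, (6, 6)),
        st.floats(0, 5),
        st.floats(0, 5),
    )
    def test_monotone_in_alpha(self, pixels, a1, a2):
        lo, hi = sorted((a1, a2))
        img = chan(pixels)
        t_dark_lo = gaussian_threshold(img, ThresholdParams(lo, "dark_objects"))
        t_dark_hi = gaussian_threshold(img, ThresholdParams(hi, "dark_objects"))
        assert t_dark_hi <= t_dark_lo
        t_br_lo = gaussian_threshold(img, ThresholdParams(lo, "bright_objects"))
        t_br_hi = gaussian_threshold(img, ThresholdParams(hi, "bright_objects"))
        assert t_br_hi >= t_br_lo

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            ThresholdParams(alpha=-1.0)


class TestDenoise:
    def test_constant_unchanged(self):
        img = chan(np.full((5, 5), 42))
        np.testing.assert_array_equal(denoise(img).pixels, img.pixels)

    def test_hot_pixel_removed(self):
        arr = np.zeros((5, 5), dtype=np.uint8)
        arr[2, 2] = 255
        assert denoise(chan(arr)).pixels.max() == 0

    def test_1x1_unchanged(self):
        img = chan([[17]])
        np.testing.assert_array_equal(denoise(img).pixels, [[17]])

    @given(hnp.arrays(np.uint8, (6, 6)))
    def test_output_within_input_range(self, pixels):
        out = denoise(chan(pixels)).pixels
        assert out.min() >= pixels.min() and out.max() <= pixels.max()


class TestBinarize:
    def test_strict_at_threshold(self):
        img = chan(np.full((3, 3), 100))
        assert not binarize(img, 100.0, "bright_objects").pixels.any()
        assert not binarize(img, 100.0, "dark_objects").pixels.any()

    def test_bright_selects_above(self):
        mask = binarize(chan([[0, 255]]), 127.5, "bright_objects")
        np.testing.assert_array_equal(mask.pixels, [[False, True]])

    def test_noise_tail_below_one_percent(self, rng):
        """With alpha=3 a pure-noise image marks ~0.135% (one-sided tail)."""
        noise = np.clip(rng.normal(100, 10, (1000, 1000)).round(), 0, 255).astype(np.uint8)
        img = chan(noise)
        t = gaussian_threshold(img, ThresholdParams(3, "bright_objects"))
        frac = binarize(img, t, "bright_objects").pixels.mean()
        assert frac < 0.01


class TestCandidateMask:
    @given(hnp.arrays(np.bool_, (5, 5)), hnp.arrays(np.bool_, (5, 5)), hnp.arrays(np.bool_, (5, 5)))
    def test_union_algebra(self, a, b, c):
        ma, mb, mc = BinaryMask(a), BinaryMask(b), BinaryMask(c)
        ab = candidate_mask(ma, mb)
        np.testing.assert_array_equal(ab.pixels, candidate_mask(mb, ma).pixels)  # commutative
        np.testing.assert_array_equal(
            candidate_mask(ab, mc).pixels,
            candidate_mask(ma, candidate_mask(mb, mc)).pixels,
        )  # associative
        np.testing.assert_array_equal(candidate_mask(ma, ma).pixels, a)  # idempotent

    def test_disjoint_disks_union(self):
        gf = np.zeros((10, 20), dtype=bool)
        rf = np.zeros((10, 20), dtype=bool)
        gf[2:5, 2:5] = True   # live cells appear in GF only
        rf[6:9, 14:17] = True
        merged = candidate_mask(BinaryMask(gf), BinaryMask(rf))
        np.testing.assert_array_equal(merged.pixels, gf | rf)

    def test_dim_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            candidate_mask(BinaryMask(np.zeros((2, 2), bool)), BinaryMask(np.zeros((3, 3), bool)))


class TestFindObjects:
    def test_empty_mask(self):
        assert find_objects(BinaryMask(np.zeros((5, 5), bool))) == []

    def test_two_disks(self):
        from skimage import draw

        mask = np.zeros((60, 60), dtype=bool)
        for center in ((15, 15), (45, 45)):
            rr, cc = draw.disk(center, 8, shape=mask.shape)
            mask[rr, cc] = True
        objs = find_objects(BinaryMask(mask))
        assert len(objs) == 2
        for o in objs:
            assert o.area_px == pytest.approx(np.pi * 64, rel=0.1)
            assert 0 < o.roundness <= 1.0
            assert o.equivalent_diameter_px == pytest.approx(2 * np.sqrt(o.area_px / np.pi))

    @given(hnp.arrays(np.bool_, st.tuples(st.integers(1, 8), st.integers(1, 8))))
    def test_matches_flood_fill_oracle(self, mask):
        objs = find_objects(BinaryMask(mask))
        oracle = flood_fill_components(mask)
        assert sorted(map(frozenset, oracle)) == sorted(o.pixel_set for o in objs)
        # conservation: areas sum to total foreground
        assert sum(o.area_px for o in objs) == int(mask.sum())

    def test_noiseless_chain_recovers_k_objects(self):
        spec = SceneSpec(n_live=7, n_dead=6, noise_sigma=0.0, seed=3)
        frame, truth = generate_scene(spec)
        analysis = analyze_frame(frame)
        assert len(analysis.objects) == truth.n_cells


class TestOtsuBaseline:
    def test_bimodal_separates_modes(self):
        arr = np.concatenate([np.full(500, 50), np.full(500, 200)]).astype(np.uint8)
        img = chan(arr.reshape(20, 50))
        t = otsu_threshold(img)
        assert 50 <= t < 200
        # strict > at T: exactly the bright mode is foreground
        assert binarize(img, t, "bright_objects").pixels.sum() == 500

    def test_constant_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t = otsu_threshold(chan(np.full((4, 4), 99)))
        assert t == 99.0
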