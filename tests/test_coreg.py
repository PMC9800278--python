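"""Affine registration, warping, tiling and Kendall correlation."""
import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cd8pet.coreg import (AffineTransform, compute_tiles, correlate_slides,
                          estimate_affine, kendall_tau, measure_tiles,
                          summarize_slide, warp_image, SlideSummary, Tile)


def random_affine(rng, scale=(0.5, 2.0), rot_deg=45.0, trans=20.0):
    th = np.deg2rad(rng.uniform(-rot_deg, rot_deg))
    s = rng.uniform(*scale)
    M = s * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return AffineTransform(M, rng.uniform(-trans, trans, 2))


class TestEstimateAffine:
    def test_identity_pairs(self):
        pts = np.array([[0.0, 0], [0, 10], [10, 0], [7, 7]])
        tfm, rmse = estimate_affine(pts, pts)
        assert np.allclose(tfm.params, AffineTransform.identity().params, atol=1e-12)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_known_transform_recovered_exactly(self, rng):
        true = random_affine(rng)
        dst = rng.uniform(0, 100, (4, 2))
        tfm, rmse = estimate_affine(dst, true.apply(dst))
        assert np.abs(tfm.params - true.params).max() < 1e-10

    def test_noiseless_recovery_over_many_random_affines(self, rng):
        for _ in range(20):
            true = random_affine(rng)
            dst = rng.uniform(0, 200, (5, 2))
            tfm, _ = estimate_affine(dst, true.apply(dst))
            assert np.abs(tfm.params - true.params).max() < 1e-8

    def test_collinear_landmarks_rejected(self):
        line = np.array([[0.0, 0], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="collinear"):
            estimate_affine(line, line)

    def test_too_few_landmarks_rejected(self):
        pts = np.array([[0.0, 0], [1, 0]])
        with pytest.raises(ValueError, match=">= 3"):
            estimate_affine(pts, pts)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.zeros((2, 2)), np.zeros(2))


class TestWarpImage:
    def test_identity_leaves_image_unchanged(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        warped, valid = warp_image(img, AffineTransform.identity(), (32, 32))
        assert np.allclose(warped, img)
        assert valid.all()

    def test_integer_translation_with_nearest(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        tfm = AffineTransform(np.eye(2), np.array([3.0, 2.0]))
        warped, valid = warp_image(img, tfm, (20, 20), "nearest")
        assert np.array_equal(warped[:17, :18], img[3:, 2:])
        assert not valid[18, 0]  # reads past the source bottom edge

    def test_round_trip_rmse_below_one_percent(self, rng):
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(rng.uniform(0, 1, (64, 64)), 4)
        tfm = AffineTransform(
            1.1 * np.array([[np.cos(0.2), -np.sin(0.2)],
                            [np.sin(0.2), np.cos(0.2)]]), np.array([2.0, -1.0]))
        fwd, _ = warp_image(img, tfm, (64, 64))
        back, valid = warp_image(np.nan_to_num(fwd), tfm.inverse(), (64, 64))
        core = valid & np.isfinite(back)
        core[:8] = core[-8:] = core[:, :8] = core[:, -8:] = False
        rmse = np.sqrt(np.nanmean((back[core] - img[core]) ** 2))
        assert rmse < 0.01 * np.ptp(img)


class TestComputeTiles:
    def test_full_roi_count_formula(self):
        tiles = compute_tiles(np.ones((512, 512), bool), 100, 50)
        per_axis = (512 - 100) // 50 + 1
        assert len(tiles) == per_axis**2

    def test_overlap_threshold_is_a_quarter(self):
        roi = np.zeros((100, 100), bool)
        roi[:20, :] = True  # 20 % of a full-image tile
        assert compute_tiles(roi, 100, 100) == []
        roi[:25, :] = True
        assert len(compute_tiles(roi, 100, 100)) == 1

    def test_empty_roi_gives_no_tiles(self):
        assert compute_tiles(np.zeros((64, 64), bool), 16, 8) == []

    def test_nonpositive_stride_rejected(self):
        with pytest.raises(ValueError):
            compute_tiles(np.ones((64, 64), bool), 16, 0)

    def test_oversized_tile_gives_no_tiles(self):
        assert compute_tiles(np.ones((64, 64), bool), 128, 64) == []


class TestMeasureTiles:
    def test_uniform_arg_equal_to_background_reads_zero(self, rng):
        shape = (64, 64)
        arg = np.full(shape, 3.3)
        ihc = rng.random(shape) < 0.2
        bg = np.zeros(shape, bool)
        bg[:8, :8] = True
        tiles = compute_tiles(np.ones(shape, bool), 16, 16)
        meas = measure_tiles(ihc, arg, tiles, bg, scan_delay_h=48.0)
        assert all(m.arg_intensity == pytest.approx(0.0, abs=1e-12) for m in meas)

    def test_all_positive_tile_reads_hundred_percent(self):
        shape = (32, 32)
        meas = measure_tiles(np.ones(shape, bool), np.ones(shape),
                             compute_tiles(np.ones(shape, bool), 16, 16))
        assert all(m.ihc_pct_positive == 100.0 for m in meas)

    def test_matches_brute_force_pixel_loops(self, rng):
        shape = (96, 96)
        ihc = rng.random(shape) < 0.3
        arg = rng.uniform(0, 5, shape)
        roi = np.zeros(shape, bool)
        roi[10:80, 5:90] = True
        for size, stride in ((16, 8), (32, 16), (48, 24)):
            tiles = compute_tiles(roi, size, stride)
            meas = measure_tiles(ihc, arg, tiles)
            for m in meas:
                r, c, s = m.tile.row0, m.tile.col0, m.tile.size_px
                pct = 0.0
                tot = 0
                acc = 0.0
                for i in range(r, r + s):
                    for j in range(c, c + s):
                        tot += 1
                        pct += ihc[i, j]
                        acc += arg[i, j]
                assert m.ihc_pct_positive == pytest.approx(100 * pct / tot)
                assert m.arg_intensity == pytest.approx(acc / tot)

    def test_tiles_without_valid_pixels_are_dropped(self):
        shape = (32, 32)
        arg = np.full(shape, np.nan)
        tiles = compute_tiles(np.ones(shape, bool), 16, 16)
        assert measure_tiles(np.ones(shape, bool), arg, tiles) == []


class TestKendallTau:
    def test_perfect_concordance_and_reversal(self):
        assert kendall_tau([1, 2, 3, 5], [2, 4, 8, 9])[0] == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3], [9, 5, 1])[0] == pytest.approx(-1.0)

    def test_enumerated_example(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(2 / 3)

    def test_exact_p_matches_enumeration(self):
        x = [1.0, 2, 3, 4, 5]
        y = [2.0, 1, 4, 3, 5]
        tau, p = kendall_tau(x, y)
        from scipy.stats import kendalltau
        taus = [kendalltau(x, np.array(y)[list(perm)]).statistic
                for perm in itertools.permutations(range(5))]
        expected = np.mean(np.abs(taus) >= abs(tau) - 1e-12)
        assert p == pytest.approx(expected)

    @given(st.sampled_from([np.exp, np.cbrt, lambda v: 5 * v - 2]))
    def test_invariance_under_monotone_transforms(self, f):
        x = np.array([0.3, 1.2, 0.9, 2.5, 1.7, 0.1])
        y = np.array([1.0, 0.4, 2.2, 1.9, 0.6, 0.2])
        base = kendall_tau(x, y)[0]
        assert kendall_tau(f(x), y)[0] == pytest.approx(base)
        assert kendall_tau(x, f(y))[0] == pytest.approx(base)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1.0, 1.0, 1.0], [1, 2, 3])


def _summary(slide_id, n_tiles, tau=0.5, seed=0):
    import pandas as pd
    rng = np.random.default_rng(seed)
    s = SlideSummary(slide_id, rng.uniform(1, 30), rng.uniform(0, 2))
    ihc = rng.uniform(0, 40, n_tiles)
    tbl = pd.DataFrame({"ihc_pct_positive": ihc,
                        "arg_intensity": ihc * 0.1 + rng.normal(0, 1, n_tiles)})
    s.tile_tables[64] = tbl
    if n_tiles >= 6:
        s.within_slide_tau[64] = kendall_tau(tbl["ihc_pct_positive"],
                                             tbl["arg_intensity"])
    return s


class TestCorrelateSlides:
    def test_small_slides_excluded_within_but_pooled(self):
        summaries = [_summary(f"S{i}", 10, seed=i) for i in range(3)]
        summaries.append(_summary("tiny", 5, seed=9))
        within = correlate_slides(summaries, "tile-within", tile_size=64)
        assert "tiny" not in set(within["per_slide"]["slide_id"])
        pooled = correlate_slides(summaries, "tile-pooled", tile_size=64)
        assert pooled["n_tiles"] == 35  # 10+10+10+5: the 5-tile slide counts

    def test_slide_level_needs_three_slides(self):
        with pytest.raises(ValueError):
            correlate_slides([_summary("a", 8), _summary("b", 8)], "slide-level")

    def test_decay_correction_invariance_across_scan_delays(self, rng):
        from cd8pet.synthetic import generate_slide_pair
        a = generate_slide_pair(noise_sd=0.0, scan_delay_h=0.0, seed=5,
                                background_level=0.0)
        b = generate_slide_pair(noise_sd=0.0, scan_delay_h=78.4, seed=5,
                                background_level=0.0)
        sa = summarize_slide("a", a.ihc_positivity, a.arg_image, a.roi_mask,
                             scan_delay_h=0.0, tile_sizes=(64,))
        sb = summarize_slide("b", b.ihc_positivity, b.arg_image, b.roi_mask,
                             scan_delay_h=78.4, tile_sizes=(64,))
        ta = sa.tile_tables[64]["arg_intensity"].to_numpy()
        tb = sb.tile_tables[64]["arg_intensity"].to_numpy()
        assert ta == pytest.approx(tb, rel=1e-9)
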