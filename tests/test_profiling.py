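"""Column profiles, disruption-center detection, re-centering, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from scratchquant import (
    BinaryMask,
    ColumnProfile,
    NoDisruptionError,
    ValidationError,
    average_profiles,
    column_profile,
    find_gap_center,
    recenter,
)


def brute_force_profile(pixels):
    """Naive double-loop per-column black/white counting."""
    h, w = pixels.shape
    bf = np.empty(w)
    bw = np.empty(w)
    for c in range(w):
        black = sum(1 for r in range(h) if not pixels[r, c])
        white = h - black
        bf[c] = black / h
        bw[c] = black / white if white else np.inf
    return bf, bw


def profile_from(bf, hour=0.0, center=None, replicate=1):
    bf = np.asarray(bf, dtype=float)
    with np.errstate(divide="ignore"):
        bw = np.where(bf < 1, bf / (1 - bf), np.inf)
    return ColumnProfile(bf, bw, hour=hour, replicate=replicate, center=center)


class TestColumnProfile:
    def test_vector_lengths_match_width(self, rng):
        mask = BinaryMask(rng.random((1200, 1600)) < 0.5)
        prof = column_profile(mask)
        assert prof.width == 1600

    def test_all_white_mask(self):
        prof = column_profile(BinaryMask(np.ones((8, 5), dtype=bool)))
        np.testing.assert_array_equal(prof.black_fraction, 0.0)
        np.testing.assert_array_equal(prof.bw_ratio, 0.0)

    def test_checkerboard_half_black(self):
        tile = np.indices((6, 8)).sum(axis=0) % 2 == 0
        prof = column_profile(BinaryMask(tile))
        np.testing.assert_allclose(prof.black_fraction, 0.5)
        np.testing.assert_allclose(prof.bw_ratio, 1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=24))
    )
    def test_matches_brute_force_oracle(self, pixels):
        prof = column_profile(BinaryMask(pixels))
        bf, bw = brute_force_profile(pixels)
        np.testing.assert_allclose(prof.black_fraction, bf, atol=1e-15)
        np.testing.assert_array_equal(prof.bw_ratio, bw)

    def test_conservation_black_plus_white_is_height(self, rng):
        mask = BinaryMask(rng.random((17, 23)) < 0.3)
        prof = column_profile(mask)
        white = mask.pixels.sum(axis=0)
        black = np.round(prof.black_fraction * mask.height)
        np.testing.assert_array_equal(black + white, mask.height)

    def test_ratio_finite_exactly_where_fraction_below_one(self, rng):
        mask = BinaryMask(rng.random((10, 40)) < 0.9)
        prof = column_profile(mask)
        np.testing.assert_array_equal(
            np.isfinite(prof.bw_ratio), prof.black_fraction < 1.0
        )


class TestFindGapCenter:
    def test_midpoint_of_inclusive_run(self):
        bf = np.zeros(1600)
        bf[700:901] = 1.0  # columns 700..900 inclusive
        assert find_gap_center(profile_from(bf)) == 800

    def test_single_all_black_column(self):
        bf = np.zeros(1024)
        bf[512] = 1.0
        assert find_gap_center(profile_from(bf)) == 512

    def test_even_run_uses_lower_median(self):
        bf = np.zeros(100)
        bf[10:14] = 1.0  # columns 10,11,12,13
        assert find_gap_center(profile_from(bf)) == 11

    def test_longest_run_wins(self):
        bf = np.zeros(200)
        bf[10:20] = 1.0
        bf[100:130] = 1.0
        assert find_gap_center(profile_from(bf)) == 114

    def test_no_disruption_raises(self):
        bf = np.full(100, 0.2)
        with pytest.raises(NoDisruptionError):
            find_gap_center(profile_from(bf))

    def test_requires_hour_zero(self):
        bf = np.zeros(100)
        bf[50] = 1.0
        with pytest.raises(ValidationError):
            find_gap_center(profile_from(bf, hour=24.0))

    def test_fallback_smoothed_argmax_warns(self):
        cols = np.arange(300)
        bf = 0.9 * np.exp(-((cols - 150) ** 2) / (2 * 30.0**2))
        with pytest.warns(UserWarning, match="no all-black column"):
            c = find_gap_center(profile_from(bf))
        assert abs(c - 150) <= 2


class TestRecenter:
    def test_identity_shift(self, rng):
        bf = rng.random(50)
        prof = profile_from(bf)
        out = recenter(prof, center=25, target_center=25, target_width=50)
        np.testing.assert_allclose(out.black_fraction, bf)

    def test_shift_bookkeeping(self, rng):
        bf = rng.random(60)
        prof = profile_from(bf)
        out = recenter(prof, center=20, target_center=30, target_width=60)
        shift = 10
        for c in range(60):
            src = c - shift
            if 0 <= src < 60:
                assert out.black_fraction[c] == bf[src]
            else:
                assert np.isnan(out.black_fraction[c])

    def test_shift_back_reproduces_overlap(self, rng):
        bf = rng.random(80)
        prof = profile_from(bf)
        fwd = recenter(prof, center=10, target_center=40, target_width=80)
        back = recenter(fwd, center=40, target_center=10, target_width=80)
        overlap = ~np.isnan(back.black_fraction)
        np.testing.assert_allclose(back.black_fraction[overlap], bf[overlap])

    def test_mirrored_replicates_average_symmetric(self):
        rng = np.random.default_rng(11)
        bf = rng.random(101)
        mirrored = bf[::-1].copy()
        width = 101
        tc = width // 2
        a = recenter(profile_from(bf), center=30, target_center=tc, target_width=width)
        b = recenter(
            profile_from(mirrored), center=100 - 30, target_center=tc, target_width=width
        )
        avg = average_profiles([a, b]).mean_black_fraction
        valid = ~np.isnan(avg) & ~np.isnan(avg[::-1])
        np.testing.assert_allclose(avg[valid], avg[::-1][valid], atol=1e-12)

    def test_rejects_bad_target_width(self):
        with pytest.raises(ValidationError):
            recenter(profile_from(np.zeros(10)), 5, 5, 0)

    def test_rejects_center_out_of_range(self):
        with pytest.raises(ValidationError):
            recenter(profile_from(np.zeros(10)), 12, 5, 10)


class TestAverageProfiles:
    def test_single_profile_mean_is_itself_dispersion_zero(self, rng):
        bf = rng.random(30)
        prof = profile_from(bf)
        avg = average_profiles([prof])
        np.testing.assert_allclose(avg.mean_black_fraction, bf)
        np.testing.assert_array_equal(avg.dispersion, 0.0)
        np.testing.assert_array_equal(avg.n_replicates, 1)

    def test_two_profiles_column_mean(self):
        a = profile_from(np.full(5, 0.2))
        b = profile_from(np.full(5, 0.6))
        avg = average_profiles([a, b])
        np.testing.assert_allclose(avg.mean_black_fraction, 0.4)

    def test_missing_columns_excluded_not_zero_filled(self):
        a = profile_from(np.full(10, 0.5))
        shifted = recenter(a, center=2, target_center=7, target_width=10)
        avg = average_profiles([shifted, profile_from(np.full(10, 0.1)).with_center(7)])
        # first 5 columns of `shifted` are missing -> mean from one replicate only
        assert np.isnan(shifted.black_fraction[:5]).all()
        np.testing.assert_allclose(avg.mean_black_fraction[:5], 0.1)
        np.testing.assert_array_equal(avg.n_replicates[:5], 1)
        np.testing.assert_allclose(avg.mean_black_fraction[5:], 0.3)
        np.testing.assert_array_equal(avg.n_replicates[5:], 2)

    def test_mean_matches_brute_force_from_masks(self, rng):
        masks = [BinaryMask(rng.random((20, 40)) < 0.5) for _ in range(5)]
        profs = [column_profile(m) for m in masks]
        avg = average_profiles(profs)
        manual = np.mean(
            [(20 - m.pixels.sum(axis=0)) / 20 for m in masks], axis=0
        )
        np.testing.assert_allclose(avg.mean_black_fraction, manual, atol=1e-12)

    def test_rejects_empty_and_mixed_hours(self):
        with pytest.raises(ValidationError):
            average_profiles([])
        with pytest.raises(ValidationError):
            average_profiles([profile_from(np.zeros(5)), profile_from(np.zeros(5), hour=24.0)])

    def test_infinite_ratios_excluded_from_ratio_mean(self):
        a = profile_from(np.array([1.0, 0.5]))  # first column all-black -> inf ratio
        b = profile_from(np.array([0.5, 0.5]))
        avg = average_profiles([a, b])
        assert avg.mean_bw_ratio[0] == 1.0  # only b contributes
        assert avg.mean_bw_ratio[1] == 1.0
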