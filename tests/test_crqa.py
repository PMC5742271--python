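import numpy as np
import pytest

from dyadrec.categorize import DETAILED, SIMPLE
from dyadrec.crqa import (
    CrqaError,
    LagProfile,
    average_profiles,
    cross_recurrence_matrix,
    lag_profile,
    lag_profile_from_matrix,
    peak_lag,
    subsample_profile,
)

from .conftest import make_series, random_series


def brute_force_profile(parent, infant, L):
    """Independent double-loop oracle for the diagonal-wise recurrence rate."""
    n = len(parent)
    out = {}
    for tau in range(-L, L + 1):
        hits = total = 0
        for t in range(n):
            s = t - tau
            if 0 <= s < n:
                total += 1
                hits += parent[t] == infant[s]
        out[tau] = 100.0 * hits / total
    return out


class TestRecurrenceMatrix:
    def test_identical_series_all_one_diagonal(self, rng):
        s = random_series(rng, 40)
        plot = cross_recurrence_matrix(s, s)
        assert np.all(np.diagonal(plot.matrix))

    def test_disjoint_codes_all_zero(self):
        parent = make_series([1] * 10)
        infant = make_series([2] * 10)
        assert not cross_recurrence_matrix(parent, infant).matrix.any()

    def test_hand_enumerated_three_by_three(self):
        parent = make_series([1, 1, 2])
        infant = make_series([1, 2, 2])
        expected = np.array([[1, 1, 0], [0, 0, 1], [0, 0, 1]], dtype=bool)
        assert np.array_equal(cross_recurrence_matrix(parent, infant).matrix, expected)

    def test_unequal_lengths_point_to_trim(self, rng):
        with pytest.raises(CrqaError, match="trim_pair"):
            cross_recurrence_matrix(random_series(rng, 10), random_series(rng, 8))

    def test_mixed_systems_rejected(self, rng):
        a = random_series(rng, 10, system=SIMPLE)
        b = random_series(rng, 10, system=DETAILED)
        with pytest.raises(CrqaError, match="system"):
            cross_recurrence_matrix(a, b)


class TestLagProfile:
    def test_identical_constant_series_saturates(self):
        s = make_series([1] * 300)
        prof = lag_profile(s, s, max_lag_s=4.0)
        assert np.all(prof.rr == 100.0)

    def test_delayed_copy_peaks_at_minus_delay(self, rng):
        parent = random_series(rng, 60)
        infant = make_series(np.concatenate([[0], parent.codes[:-1]]))
        prof = lag_profile(parent, infant, max_lag_s=2 / 25.0)  # L = 2
        oracle = brute_force_profile(parent.codes, infant.codes, 2)
        for k, tau in enumerate(prof.lags):
            assert prof.rr[k] == pytest.approx(oracle[tau])
        assert prof.rr[list(prof.lags).index(-1)] == 100.0
        assert (prof.rr < 100.0).sum() == len(prof) - 1  # strict max

    def test_four_second_window_gives_201_bins(self, rng):
        prof = lag_profile(random_series(rng, 500), random_series(rng, 500), 4.0)
        assert len(prof) == 201
        assert prof.lags[0] == -100 and prof.lags[-1] == 100

    def test_per_diagonal_overlap_normalization(self, rng):
        prof = lag_profile(random_series(rng, 300), random_series(rng, 300), 4.0)
        assert np.array_equal(prof.n_overlap, 300 - np.abs(prof.lags))

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(CrqaError, match="lag window"):
            lag_profile(random_series(rng, 90), random_series(rng, 90), 4.0)

    def test_reversal_duality(self, rng):
        a = random_series(rng, 200)
        b = random_series(rng, 200)
        ab = lag_profile(a, b, 1.0)
        ba = lag_profile(b, a, 1.0)
        np.testing.assert_allclose(ab.rr, ba.rr[::-1])

    def test_matrix_route_equals_direct_route_exactly(self, rng):
        for _ in range(10):
            n = int(rng.integers(120, 400))
            a = random_series(rng, n, system=DETAILED)
            b = random_series(rng, n, system=DETAILED)
            direct = lag_profile(a, b, 4.0)
            via_matrix = lag_profile_from_matrix(cross_recurrence_matrix(a, b), 4.0)
            np.testing.assert_array_equal(direct.rr, via_matrix.rr)

    def test_independent_series_match_analytic_chance_level(self, rng):
        # E[rr] = 100 * sum_c p_c q_c for independent i.i.d. series
        rrs = []
        for _ in range(40):
            a = random_series(rng, 400)
            b = random_series(rng, 400)
            rrs.append(lag_profile(a, b, 0.4).rr.mean())
        assert np.mean(rrs) == pytest.approx(100 / 3, abs=0.5)

    def test_lag_ms_conversion(self, rng):
        prof = lag_profile(random_series(rng, 300), random_series(rng, 300), 1.0)
        assert prof.lag_ms[0] == -1000.0
        assert prof.lag_ms[list(prof.lags).index(6)] == 240.0


class TestSubsample:
    def test_201_bins_to_51(self, rng):
        prof = lag_profile(random_series(rng, 500), random_series(rng, 500), 4.0)
        sub = subsample_profile(prof, 6.25)
        assert len(sub) == 51

    def test_target_equal_fps_is_identity(self, rng):
        prof = lag_profile(random_series(rng, 300), random_series(rng, 300), 2.0)
        sub = subsample_profile(prof, prof.fps)
        np.testing.assert_array_equal(sub.lags, prof.lags)
        np.testing.assert_array_equal(sub.rr, prof.rr)

    def test_kept_lags_are_the_stride_grid(self, rng):
        prof = lag_profile(random_series(rng, 500), random_series(rng, 500), 4.0)
        sub = subsample_profile(prof, 6.25)
        assert list(sub.lags) == list(range(-100, 101, 4))

    def test_non_integer_stride_rejected(self, rng):
        prof = lag_profile(random_series(rng, 300), random_series(rng, 300), 2.0)
        with pytest.raises(CrqaError):
            subsample_profile(prof, 6.0)


class TestPeakLag:
    def test_unique_peak_reported_in_ms_with_leader(self):
        lags = np.arange(-10, 11)
        rr = np.exp(-0.5 * (lags + 6) ** 2)
        prof = LagProfile(lags, rr, 300 - np.abs(lags), fps=25.0)
        ms, leader = peak_lag(prof)
        assert ms == -240.0
        assert leader == "parent-leading"

    def test_peak_at_zero_is_synchronous(self):
        lags = np.arange(-5, 6)
        rr = 10 - np.abs(lags)
        prof = LagProfile(lags, rr, 100 - np.abs(lags), fps=25.0)
        assert peak_lag(prof) == (0.0, "synchronous")

    def test_argmax_agrees_with_exhaustive_scan(self, rng):
        for _ in range(25):
            lags = np.arange(-20, 21)
            rr = rng.uniform(0, 100, size=len(lags))
            prof = LagProfile(lags, rr, 500 - np.abs(lags), fps=25.0)
            ms, _ = peak_lag(prof)
            assert ms == 1000.0 * lags[int(np.argmax(rr))] / 25.0

    def test_all_equal_rr_ties_to_zero_with_warning(self):
        lags = np.arange(-3, 4)
        prof = LagProfile(lags, np.full(7, 42.0), 50 - np.abs(lags), fps=25.0)
        with pytest.warns(UserWarning, match="tie"):
            ms, leader = peak_lag(prof)
        assert ms == 0.0 and leader == "synchronous"

    def test_symmetric_tie_resolves_negative(self):
        lags = np.arange(-2, 3)
        rr = np.array([1.0, 9.0, 5.0, 9.0, 1.0])
        prof = LagProfile(lags, rr, 50 - np.abs(lags), fps=25.0)
        with pytest.warns(UserWarning):
            ms, leader = peak_lag(prof)
        assert ms == -40.0 and leader == "parent-leading"


class TestAverageProfiles:
    def _profile(self, rr, fps=25.0):
        lags = np.arange(-len(rr) // 2 + 1, len(rr) // 2 + 1)
        return LagProfile(lags, np.asarray(rr, float), 100 - np.abs(lags), fps=fps)

    def test_single_profile_mean_is_input_sd_zero(self):
        p = self._profile([10.0, 20.0, 30.0, 20.0, 10.0])
        mean, sd = average_profiles([p])
        np.testing.assert_array_equal(mean.rr, p.rr)
        assert np.all(sd == 0)

    def test_two_flat_profiles_average_midway(self):
        mean, _ = average_profiles([self._profile([40.0] * 5), self._profile([60.0] * 5)])
        assert np.all(mean.rr == 50.0)

    def test_21_profiles_match_direct_summation(self, rng):
        profs = [self._profile(rng.uniform(0, 100, 9)) for _ in range(21)]
        mean, sd = average_profiles(profs)
        stack = np.vstack([p.rr for p in profs])
        np.testing.assert_allclose(mean.rr, stack.sum(axis=0) / 21)
        np.testing.assert_allclose(sd, stack.std(axis=0))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(CrqaError):
            average_profiles([self._profile([1.0] * 5), self._profile([1.0] * 7)])
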