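import numpy as np
import pytest

from dyadrec.trajectory import (
    BoundingBox,
    BoxTrajectory,
    TrajectoryError,
    interpolate_gaps,
    load_trajectory,
    save_trajectory,
    tracking_accuracy,
    trim_pair,
)

from .conftest import make_series, make_trajectory, random_series


class TestLoadTrajectory:
    def test_empty_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(TrajectoryError):
            load_trajectory(p)

    def test_reads_fully_valid_file_verbatim(self, tmp_path):
        p = tmp_path / "traj.csv"
        lines = ["frame,x,y,w,h,valid"] + [f"{i},{i * 2},{i * 3},10,12,1" for i in range(10)]
        p.write_text("\n".join(lines))
        traj = load_trajectory(p, fps=25.0)
        assert len(traj) == 10
        assert traj.valid.all()
        assert np.array_equal(traj.x, 2 * np.arange(10))

    def test_missing_frames_become_invalid_placeholders(self, tmp_path):
        p = tmp_path / "gap.csv"
        rows = [f"{i},{i},0,5,5,1" for i in (0, 1, 4, 5)]
        p.write_text("frame,x,y,w,h,valid\n" + "\n".join(rows))
        traj = load_trajectory(p)
        assert len(traj) == 6
        assert list(traj.valid) == [True, True, False, False, True, True]

    def test_round_trip_preserves_fields(self, tmp_path, rng):
        centers = rng.uniform(0, 100, size=(20, 2))
        valid = rng.random(20) > 0.3
        valid[[0, -1]] = True
        traj = make_trajectory(centers, valid=valid)
        path = tmp_path / "rt.csv"
        save_trajectory(traj, path)
        back = load_trajectory(path, fps=traj.fps)
        np.testing.assert_allclose(back.x, traj.x)
        np.testing.assert_allclose(back.y, traj.y)
        np.testing.assert_allclose(back.w, traj.w)
        np.testing.assert_allclose(back.h, traj.h)
        assert np.array_equal(back.valid, traj.valid)

    def test_duplicate_frame_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("frame,x,y,w,h,valid\n0,0,0,5,5,1\n1,1,0,5,5,1\n1,2,0,5,5,1\n")
        with pytest.raises(TrajectoryError, match="duplicate"):
            load_trajectory(p)

    def test_malformed_row_names_location(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,x,y,w,h,valid\n0,0,0,5,5,1\n1,oops,0,5,5,1\n")
        with pytest.raises(TrajectoryError, match="x"):
            load_trajectory(p)

    def test_single_row_rejected(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("frame,x,y,w,h,valid\n0,0,0,5,5,1\n")
        with pytest.raises(TrajectoryError):
            load_trajectory(p)


class TestTrackingAccuracy:
    def test_all_valid_is_100(self):
        traj = make_trajectory(np.zeros((10, 2)) + 5)
        assert tracking_accuracy(traj) == 100.0

    def test_ten_percent_invalid_is_90(self):
        valid = np.ones(100, dtype=bool)
        valid[5:15] = False
        traj = make_trajectory(np.tile([5.0, 5.0], (100, 1)), valid=valid)
        assert tracking_accuracy(traj) == 90.0

    def test_matches_direct_count_under_random_dropout(self, rng):
        valid = rng.random(1000) >= 0.2
        valid[[0, -1]] = True
        traj = make_trajectory(rng.uniform(0, 50, (1000, 2)), valid=valid)
        expected = 100.0 * sum(1 for v in valid if v) / 1000
        assert tracking_accuracy(traj) == pytest.approx(expected)

    def test_invalidating_a_frame_never_raises_accuracy(self, rng):
        valid = rng.random(50) > 0.1
        valid[[0, -1]] = True
        traj = make_trajectory(rng.uniform(0, 50, (50, 2)), valid=valid)
        before = tracking_accuracy(traj)
        idx = int(np.flatnonzero(valid)[1])
        worse = valid.copy()
        worse[idx] = False
        traj2 = make_trajectory(traj.centers, valid=worse)
        assert tracking_accuracy(traj2) <= before


class TestInterpolateGaps:
    def test_interior_gap_linear(self):
        centers = np.array([[0.0, 0.0], [99.0, 99.0], [99.0, 99.0], [6.0, 0.0]])
        valid = [True, False, False, True]
        repaired, n = interpolate_gaps(make_trajectory(centers, valid=valid))
        assert n == 2
        np.testing.assert_allclose(repaired.centers[1], [2.0, 0.0])
        np.testing.assert_allclose(repaired.centers[2], [4.0, 0.0])
        assert repaired.valid.all()

    def test_no_gaps_is_identity(self, rng):
        traj = make_trajectory(rng.uniform(0, 50, (30, 2)))
        repaired, n = interpolate_gaps(traj)
        assert n == 0
        np.testing.assert_array_equal(repaired.centers, traj.centers)

    def test_interpolated_centers_lie_on_bracketing_segments(self, rng):
        valid = rng.random(200) > 0.3
        valid[[0, -1]] = True
        centers = rng.uniform(0, 100, (200, 2))
        repaired, _ = interpolate_gaps(make_trajectory(centers, valid=valid))
        vi = np.flatnonzero(valid)
        for t in np.flatnonzero(~valid):
            lo = vi[vi < t].max()
            hi = vi[vi > t].min()
            a, b, c = centers[lo], centers[hi], repaired.centers[t]
            frac = (t - lo) / (hi - lo)
            np.testing.assert_allclose(c, a + frac * (b - a), atol=1e-9)

    def test_idempotent(self, rng):
        valid = rng.random(60) > 0.25
        valid[[0, -1]] = True
        once, _ = interpolate_gaps(make_trajectory(rng.uniform(0, 50, (60, 2)), valid=valid))
        twice, n2 = interpolate_gaps(once)
        assert n2 == 0
        np.testing.assert_array_equal(once.centers, twice.centers)

    def test_edge_gap_extrapolates_with_warning(self):
        centers = np.array([[9.0, 9.0], [5.0, 5.0], [7.0, 7.0]])
        valid = [False, True, True]
        with pytest.warns(UserWarning, match="boundary"):
            repaired, n = interpolate_gaps(make_trajectory(centers, valid=valid))
        assert n == 1
        np.testing.assert_allclose(repaired.centers[0], [5.0, 5.0])

    def test_all_invalid_is_unrecoverable(self):
        with pytest.raises(TrajectoryError):
            interpolate_gaps(make_trajectory(np.zeros((5, 2)) + 3, valid=[False] * 5))


class TestTrimPair:
    def test_trims_longer_to_shorter(self, rng):
        a = random_series(rng, 1027)
        b = random_series(rng, 375)
        ta, tb = trim_pair(a, b)
        assert len(ta) == len(tb) == 375

    def test_equal_lengths_unchanged(self, rng):
        a = random_series(rng, 100)
        b = random_series(rng, 100)
        ta, tb = trim_pair(a, b)
        assert np.array_equal(ta.codes, a.codes)
        assert np.array_equal(tb.codes, b.codes)

    def test_only_trailing_elements_removed(self, rng):
        a = random_series(rng, 10)
        b = make_series(a.codes[:7])
        ta, tb = trim_pair(a, b)
        assert np.array_equal(ta.codes, b.codes)

    def test_fps_mismatch_rejected(self, rng):
        a = random_series(rng, 10)
        b = make_series(a.codes[:7], fps=30.0)
        with pytest.raises(TrajectoryError, match="fps"):
            trim_pair(a, b)

    def test_output_lengths_equal_min_for_random_pairs(self, rng):
        for _ in range(20):
            na, nb = rng.integers(2, 200, size=2)
            ta, tb = trim_pair(random_series(rng, na), random_series(rng, nb))
            assert len(ta) == len(tb) == min(na, nb)


class TestBoundingBoxInvariants:
    def test_valid_box_needs_positive_size(self):
        with pytest.raises(TrajectoryError):
            BoundingBox(0, 0.0, 0.0, 0.0, 5.0, valid=True)

    def test_invalid_box_tolerates_degenerate_size(self):
        BoundingBox(0, np.nan, np.nan, 0.0, 0.0, valid=False)

    def test_negative_frame_rejected(self):
        with pytest.raises(TrajectoryError):
            BoundingBox(-1, 0.0, 0.0, 5.0, 5.0)

    def test_trajectory_needs_two_frames(self):
        with pytest.raises(TrajectoryError):
            BoxTrajectory(
                x=np.array([1.0]), y=np.array([1.0]), w=np.array([5.0]),
                h=np.array([5.0]), valid=np.array([True]),
            )
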