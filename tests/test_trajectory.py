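import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movesoc.trajectory import (
    MetricsConfig,
    PathSegment,
    compute_daily_metrics,
    daily_metrics,
    project_to_plane,
    read_gps,
    resample,
    residence_time,
    sinuosity,
    split_segments,
    step_lengths,
    turning_angles,
    unproject_from_plane,
)

from conftest import random_segment
from oracles import (
    haversine_m,
    residence_focal_is_knife_edge,
    residence_time_bruteforce,
)


# ---------------------------------------------------------------------------
# projection

class TestProjection:
    def test_origin_maps_to_zero(self):
        x, y = project_to_plane(np.array([18.4]), np.array([-34.15]), (18.4, -34.15))
        assert x[0] == 0.0 and y[0] == 0.0

    def test_matches_haversine(self):
        # 0.001 deg of latitude is ~111.2 m
        x, y = project_to_plane(
            np.array([18.4, 18.4]), np.array([-34.15, -34.149]), (18.4, -34.15)
        )
        d_proj = math.hypot(x[1] - x[0], y[1] - y[0])
        d_hav = haversine_m(18.4, -34.15, 18.4, -34.149)
        assert d_proj == pytest.approx(111.2, abs=0.3)
        assert d_proj == pytest.approx(d_hav, rel=1e-4)

    def test_random_pairs_match_haversine(self):
        rng = np.random.default_rng(0)
        lon = 18.4 + rng.uniform(-0.05, 0.05, 20)
        lat = -34.15 + rng.uniform(-0.05, 0.05, 20)
        x, y = project_to_plane(lon, lat, (18.4, -34.15))
        for i in range(19):
            d_proj = math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
            d_hav = haversine_m(lon[i], lat[i], lon[i + 1], lat[i + 1])
            assert d_proj == pytest.approx(d_hav, rel=2e-3)

    def test_round_trip_sub_decimetre(self):
        rng = np.random.default_rng(1)
        lon = 18.4 + rng.uniform(-0.05, 0.05, 50)
        lat = -34.15 + rng.uniform(-0.05, 0.05, 50)
        x, y = project_to_plane(lon, lat, (18.4, -34.15))
        lon2, lat2 = unproject_from_plane(x, y, (18.4, -34.15))
        back_x, back_y = project_to_plane(lon2, lat2, (18.4, -34.15))
        err = np.hypot(back_x - x, back_y - y)
        assert err.max() < 0.1

    def test_distant_fixes_warn(self):
        with pytest.warns(UserWarning, match="distort"):
            project_to_plane(np.array([20.0]), np.array([-34.0]), (18.4, -34.15))

    def test_invalid_latitude_rejected(self):
        with pytest.raises(ValueError):
            project_to_plane(np.array([0.0]), np.array([95.0]))

    def test_planar_input_passes_through_read_gps(self):
        df = pd.DataFrame(
            {
                "individual_id": ["a", "a"],
                "timestamp": ["2018-07-01T07:00:00Z", "2018-07-01T07:00:01Z"],
                "x": [1.5, 2.5],
                "y": [0.0, 0.5],
                "habitat": ["natural", "natural"],
            }
        )
        out = read_gps(df)
        assert list(out["x"]) == [1.5, 2.5]
        assert list(out["y"]) == [0.0, 0.5]


# ---------------------------------------------------------------------------
# resampling

class TestResample:
    def test_one_hz_to_minutes(self):
        t = np.arange(600.0)
        out = resample(t, t * 0.1, t * 0.0, 60.0)
        # grid anchored at the first fix: one point per minute boundary
        assert len(out) == 11
        assert np.allclose(np.diff(out["t"]), 60.0)
        # exact boundary fixes keep their positions; the trailing slot takes
        # its nearest fix (t=599) snapped onto the grid
        assert np.allclose(out["x"].iloc[:-1], out["t"].iloc[:-1] * 0.1)
        assert out["x"].iloc[-1] == pytest.approx(59.9)

    def test_gap_splits_segments(self):
        t = np.concatenate([np.arange(300.0), 900.0 + np.arange(300.0)])
        out = resample(t, np.zeros_like(t), np.zeros_like(t), 60.0)
        segs = split_segments(out, 60.0)
        assert len(segs) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 3000, 200))
        x, y = rng.normal(size=200), rng.normal(size=200)
        once = resample(t, x, y, 60.0)
        twice = resample(
            once["t"].to_numpy(), once["x"].to_numpy(), once["y"].to_numpy(), 60.0
        )
        pd.testing.assert_frame_equal(once.reset_index(drop=True), twice)

    def test_empty_input(self):
        out = resample(np.array([]), np.array([]), np.array([]), 60.0)
        assert len(out) == 0

    def test_habitat_break_splits(self):
        t = np.arange(0.0, 600.0, 60.0)
        hab = np.array(["natural"] * 5 + ["urban"] * 5)
        out = resample(t, t, t, 60.0, habitat=hab)
        segs = split_segments(out, 60.0)
        assert [s.habitat for s in segs] == ["natural", "urban"]

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            resample(np.array([0.0]), np.array([0.0]), np.array([0.0]), 0.0)


# ---------------------------------------------------------------------------
# per-segment metrics

def _seg(points, interval=60.0):
    pts = np.asarray(points, dtype=float)
    return PathSegment(
        t=np.arange(len(pts)) * interval, x=pts[:, 0], y=pts[:, 1]
    )


class TestStepLengths:
    def test_three_four_five(self):
        assert step_lengths(_seg([(0, 0), (3, 4)])).tolist() == [5.0]

    def test_stationary(self):
        assert np.all(step_lengths(_seg([(1, 1)] * 4)) == 0.0)

    def test_sum_equals_cumulative_length(self):
        rng = np.random.default_rng(4)
        seg = random_segment(rng)
        total = 0.0
        for i in range(len(seg.x) - 1):
            total += math.hypot(seg.x[i + 1] - seg.x[i], seg.y[i + 1] - seg.y[i])
        assert step_lengths(seg).sum() == pytest.approx(total, rel=1e-12)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            step_lengths(_seg([(0, 0)]))


class TestTurningAngles:
    def test_collinear_is_zero(self):
        seg = _seg([(0, 0), (1, 0), (2, 0), (3, 0)])
        assert np.allclose(turning_angles(seg), 0.0)

    def test_left_turn_positive_half_pi(self):
        seg = _seg([(0, 0), (1, 0), (1, 1)])
        assert turning_angles(seg)[0] == pytest.approx(np.pi / 2)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        seg = random_segment(rng, n=20)
        theta = 1.234
        c, s = math.cos(theta), math.sin(theta)
        rotated = PathSegment(
            t=seg.t, x=c * seg.x - s * seg.y, y=s * seg.x + c * seg.y
        )
        assert np.allclose(turning_angles(seg), turning_angles(rotated), atol=1e-9)

    def test_duplicate_positions_collapsed(self):
        seg = _seg([(0, 0), (1, 0), (1, 0), (2, 0)])
        assert np.allclose(turning_angles(seg), 0.0)


class TestSinuosity:
    def test_straight_path_zero(self):
        assert sinuosity(_seg([(0, 0), (1, 0), (2, 0), (3, 0)])) == 0.0

    def test_unit_zigzag_is_two(self):
        # p = 1 m, alternating +/-90 deg turns -> mean cos = 0 -> S = 2
        pts = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2)]
        assert sinuosity(_seg(pts)) == pytest.approx(2.0, abs=1e-12)

    def test_scaling_law(self):
        rng = np.random.default_rng(6)
        seg = random_segment(rng, n=25)
        s1 = sinuosity(seg)
        for k in (0.5, 3.0, 10.0):
            scaled = PathSegment(t=seg.t, x=k * seg.x, y=k * seg.y)
            assert sinuosity(scaled) == pytest.approx(s1 / math.sqrt(k), rel=1e-9)

    def test_back_and_forth_undefined(self):
        seg = _seg([(0, 0), (1, 0), (0, 0), (1, 0), (0, 0)])
        with pytest.warns(UserWarning, match="undefined"):
            assert sinuosity(seg) is None


class TestResidenceTime:
    def test_stationary_full_duration(self):
        n = 61  # 60 min at 1-min sampling
        seg = PathSegment(t=np.arange(n) * 60.0, x=np.zeros(n), y=np.zeros(n))
        rt = residence_time(seg, radius=1.0, cutoff=300.0)
        assert np.allclose(rt, 60.0)

    def test_straight_line_interior_points(self):
        # constant speed, radius = one step: inside only during adjacent steps
        n = 20
        seg = PathSegment(t=np.arange(n) * 60.0, x=np.arange(n) * 10.0, y=np.zeros(n))
        rt = residence_time(seg, radius=10.0, cutoff=300.0)
        interior = rt[2:-2]
        assert np.allclose(interior, 2.0, atol=1e-6)

    def test_loop_cutoff_rule(self):
        # dwell at origin 5 min, leave for `away` minutes, dwell 5 min again
        def build(away_min):
            t, x = [], []
            tt = 0.0
            for _ in range(6):
                t.append(tt); x.append(0.0); tt += 60.0
            n_away = int(away_min)
            for k in range(n_away):
                t.append(tt); x.append(50.0); tt += 60.0
            for _ in range(6):
                t.append(tt); x.append(0.0); tt += 60.0
            return PathSegment(
                t=np.array(t), x=np.array(x), y=np.zeros(len(t))
            )

        short = build(4)   # 4-min excursion (plus crossing time) < 5-min cutoff? no:
        long = build(6)
        rt_short = residence_time(short, radius=5.0, cutoff=300.0)
        rt_long = residence_time(long, radius=5.0, cutoff=300.0)
        # the first fix of the long-excursion path must not see the second visit
        assert rt_long[0] < rt_short[0]
        oracle_s = residence_time_bruteforce(short.t, short.x, short.y, 5.0, 300.0)
        oracle_l = residence_time_bruteforce(long.t, long.x, long.y, 5.0, 300.0)
        assert np.abs(rt_short - oracle_s).max() <= 3 / 60
        assert np.abs(rt_long - oracle_l).max() <= 3 / 60

    def test_minimum_fixes_enforced(self):
        seg = PathSegment(t=np.arange(4) * 60.0, x=np.zeros(4), y=np.zeros(4))
        with pytest.raises(ValueError):
            residence_time(seg, radius=1.0, cutoff=300.0)

    def test_bruteforce_oracle_on_random_segments(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            seg = random_segment(rng, n=int(rng.integers(5, 40)))
            radius = float(np.mean(step_lengths(seg))) or 1.0
            rt = residence_time(seg, radius=radius, cutoff=300.0)
            oracle = residence_time_bruteforce(seg.t, seg.x, seg.y, radius, 300.0)
            for i in range(len(seg)):
                if residence_focal_is_knife_edge(
                    seg.t, seg.x, seg.y, i, radius, 300.0
                ):
                    continue    # excursion gap on the cutoff knife edge
                # 1 s per visit: count the disc's inside runs at 1-s resolution
                tt = np.arange(seg.t[0], seg.t[-1] + 0.5)
                xx = np.interp(tt, seg.t, seg.x)
                yy = np.interp(tt, seg.t, seg.y)
                inside = (xx - seg.x[i]) ** 2 + (yy - seg.y[i]) ** 2 <= radius**2
                n_visits = max(1, int(np.diff(inside.astype(int)).clip(0).sum()) + 1)
                assert abs(rt[i] - oracle[i]) <= n_visits * 1.0 / 60.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        seg = random_segment(rng, n=20)
        theta, dx, dy = 0.7, 100.0, -50.0
        c, s = math.cos(theta), math.sin(theta)
        moved = PathSegment(
            t=seg.t, x=c * seg.x - s * seg.y + dx, y=s * seg.x + c * seg.y + dy
        )
        rt1 = residence_time(seg, 8.0, 300.0)
        rt2 = residence_time(moved, 8.0, 300.0)
        assert np.allclose(rt1, rt2, atol=1e-6)


# ---------------------------------------------------------------------------
# daily metrics

class TestDailyMetrics:
    def _day(self, t, x, y, habitat="natural"):
        return pd.DataFrame(
            {"t": t, "x": x, "y": y, "habitat": [habitat] * len(t)}
        )

    def test_all_urban_day(self):
        t = np.arange(0.0, 1200.0, 60.0)
        day = self._day(t, t * 0.5, np.zeros_like(t), habitat="urban")
        m = daily_metrics(day, "a", "2018-07-01")
        assert m.total_distance_m > 0
        assert m.median_step_m is None
        assert m.median_sinuosity is None
        assert m.median_residence_min is None

    def test_straight_natural_segment(self):
        t = np.arange(0.0, 1200.0, 60.0)
        day = self._day(t, t * 0.5, np.zeros_like(t))
        m = daily_metrics(day, "a", "2018-07-01")
        assert m.median_sinuosity == 0.0
        assert m.median_step_m == pytest.approx(30.0)

    def test_total_distance_includes_urban(self):
        t = np.arange(0.0, 1200.0, 60.0)
        hab = np.array(["natural"] * 10 + ["urban"] * 10)
        day = pd.DataFrame({"t": t, "x": t * 0.5, "y": 0.0, "habitat": hab})
        m = daily_metrics(day, "a", "2018-07-01")
        # one 30 m step is lost at the habitat break (segments never span it)
        assert m.total_distance_m == pytest.approx(30.0 * 18)

    def test_hand_computed_medians(self):
        # two natural segments separated by a gap, piecewise-known values
        t1 = np.arange(0.0, 360.0, 60.0)            # 6 fixes straight, 10 m steps
        x1 = np.arange(6) * 10.0
        t2 = np.arange(3600.0, 3960.0, 60.0)        # 6 fixes straight, 20 m steps
        x2 = 1000.0 + np.arange(6) * 20.0
        day = self._day(
            np.concatenate([t1, t2]), np.concatenate([x1, x2]),
            np.zeros(12),
        )
        m = daily_metrics(day, "a", "2018-07-01")
        steps = [10.0] * 5 + [20.0] * 5
        assert m.median_step_m == pytest.approx(float(np.median(steps)))
        assert m.median_sinuosity == 0.0
        assert m.total_distance_m == pytest.approx(150.0)

    def test_rigid_motion_invariance_of_daily_metrics(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 1800.0, 60.0)
        x = np.cumsum(rng.normal(0, 8, len(t)))
        y = np.cumsum(rng.normal(0, 8, len(t)))
        day = self._day(t, x, y)
        theta = 0.5
        c, s = math.cos(theta), math.sin(theta)
        day2 = self._day(t, c * x - s * y + 500, s * x + c * y - 200)
        m1 = daily_metrics(day, "a", "d")
        m2 = daily_metrics(day2, "a", "d")
        assert m1.total_distance_m == pytest.approx(m2.total_distance_m, rel=1e-9)
        assert m1.median_step_m == pytest.approx(m2.median_step_m, rel=1e-9)
        assert m1.median_residence_min == pytest.approx(
            m2.median_residence_min, rel=1e-9
        )

    def test_two_state_correlation_signs(self, small_sim):
        metrics = compute_daily_metrics(small_sim.gps)
        sub = metrics.dropna(
            subset=["median_step_m", "median_sinuosity", "median_residence_min"]
        )
        assert len(sub) > 20
        assert sub["median_residence_min"].corr(sub["median_step_m"]) < 0
        assert sub["median_residence_min"].corr(sub["median_sinuosity"]) > 0


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_sinuosity_scaling_property(seed):
    rng = np.random.default_rng(seed)
    seg = random_segment(rng, n=12)
    base = sinuosity(seg)
    if base is None or base == 0.0:
        return
    k = float(rng.uniform(0.1, 20.0))
    scaled = PathSegment(t=seg.t, x=k * seg.x, y=k * seg.y)
    assert sinuosity(scaled) == pytest.approx(base / math.sqrt(k), rel=1e-9)
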