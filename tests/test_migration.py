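import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import GD725, make_track, straight_track
from contactguide.conditions import CONTROL
from contactguide.migration import (
    angular_displacement,
    average_speed,
    cohort_ratio_curve,
    directional_displacement_ratio,
    directional_orientation,
    directional_speeds,
    directionality_ratio,
    filter_trajectories,
    mean_squared_displacement,
    turning_histogram,
    velocity_autocorrelation,
)
from contactguide.synthetic import SimulationParams, simulate_trajectories


class TestFilters:
    def test_short_track_excluded(self):
        short = straight_track(35, (1, 0))  # 350 min
        long = straight_track(60, (1, 0))
        kept, log = filter_trajectories([short, long])
        assert kept == [long] and log.too_short == ["t"]

    def test_off_pattern_excluded_on_grooves_only(self):
        off_groove = straight_track(60, (1, 0), condition=GD725, on_pattern=False, cell_id="og")
        off_control = straight_track(60, (1, 0), condition=CONTROL, on_pattern=False, cell_id="oc")
        kept, log = filter_trajectories([off_groove, off_control])
        assert [t.cell_id for t in kept] == ["oc"]
        assert log.off_pattern == ["og"]


class TestDirectionalOrientation:
    @pytest.mark.parametrize("net, expected", [((0, 10), 0.0), ((10, 0), 90.0), ((5, 5), 45.0)])
    def test_net_displacement_angle(self, net, expected):
        track = make_track(np.linspace((0, 0), net, 61))
        assert directional_orientation(track) == pytest.approx(expected, abs=1e-9)

    def test_zero_net_displacement_undefined(self):
        loop = make_track([(0, 0), (1, 0), (1, 1), (0, 1)] * 16 + [(0, 0)])
        with pytest.raises(ValueError, match="zero net displacement"):
            directional_orientation(loop)

    def test_duration_gate(self):
        short = straight_track(30, (0, 1))  # 300 min < 600
        with pytest.raises(ValueError, match="gate"):
            directional_orientation(short)
        assert directional_orientation(short, min_duration_min=None) == 0.0


class TestAngularDisplacement:
    def test_parallel_orthogonal_antiparallel(self):
        # consecutive displacement pairs (0,1)->(0,1), (1,0)->(0,1), (0,1)->(0,-1)
        t1 = make_track([(0, 0), (0, 1), (0, 2)])
        t2 = make_track([(0, 0), (1, 0), (1, 1)])
        t3 = make_track([(0, 0), (0, 1), (0, 0)])
        assert angular_displacement(t1, 10).values_deg[0] == pytest.approx(0.0)
        assert angular_displacement(t2, 10).values_deg[0] == pytest.approx(90.0)
        assert angular_displacement(t3, 10).values_deg[0] == pytest.approx(180.0)

    def test_zero_magnitude_pairs_skipped_and_counted(self):
        t = make_track([(0, 0), (0, 0), (0, 1), (0, 2)])
        res = angular_displacement(t, 10)
        assert res.n_skipped == 1 and len(res.values_deg) == 1

    def test_off_grid_delta_rejected(self):
        t = straight_track(10, (0, 1))
        with pytest.raises(ValueError, match="multiple"):
            angular_displacement(t, 15.0)

    def test_values_bounded(self, rng):
        t = make_track(np.cumsum(rng.normal(size=(40, 2)), axis=0))
        vals = angular_displacement(t, 20).values_deg
        assert np.all((vals >= 0) & (vals <= 180))


class TestTurningHistogram:
    def test_all_forward(self):
        h = turning_histogram(np.zeros(10), delta_min=10)
        assert h.fractions[0] == 1.0 and len(h.fractions) == 12

    def test_forward_backward_split(self):
        h = turning_histogram([0.0, 180.0])
        assert h.fractions[0] == 0.5 and h.fractions[-1] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            turning_histogram([])


class TestSpeeds:
    def test_average_speed_path_over_time(self):
        t = make_track([(0, 0), (3, 4)])
        assert average_speed(t) == pytest.approx(0.5)

    def test_stationary_zero(self):
        assert average_speed(make_track([(0, 0), (0, 0), (0, 0)])) == 0.0

    def test_two_unit_steps(self):
        t = make_track([(0, 0), (1, 0), (2, 0)])
        assert average_speed(t) == pytest.approx(0.1)

    def test_decomposition(self):
        t = make_track([(0, 0), (3, 4)])
        sp = directional_speeds(t)
        assert sp.v_x_um_per_min == pytest.approx(0.3)
        assert sp.v_y_um_per_min == pytest.approx(0.4)

    def test_pure_axial_motion_flags_infinite_ratio(self):
        sp = directional_speeds(straight_track(6, (0, 1)))
        assert sp.v_x_um_per_min == 0.0
        assert not sp.ratio_defined and np.isinf(sp.ratio_y_over_x)

    def test_square_loop_ratio_one(self):
        t = make_track([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        sp = directional_speeds(t)
        assert sp.ratio_y_over_x == pytest.approx(1.0)


class TestDisplacementRatios:
    def test_straight_axial_motion(self):
        t = straight_track(10, (0, 1))
        for delta in (10, 50, 100):
            assert directional_displacement_ratio(t, delta) == pytest.approx(1.0)
            assert directionality_ratio(t, delta) == pytest.approx(1.0)

    def test_perpendicular_motion_zero(self):
        t = straight_track(10, (1, 0))
        assert directional_displacement_ratio(t, 50) == pytest.approx(0.0)

    def test_printed_toy_path(self):
        # steps +y,+y,+y,-y over 40 min: d_y = 2, D = 4
        t = make_track([(0, 0), (0, 1), (0, 2), (0, 3), (0, 2)])
        assert directional_displacement_ratio(t, 40) == pytest.approx(0.5)
        assert directionality_ratio(t, 40) == pytest.approx(0.5)

    def test_closed_loop_directionality_zero(self):
        t = make_track([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert directionality_ratio(t, 40) == pytest.approx(0.0)

    def test_stationary_rejected(self):
        t = make_track([(0, 0), (0, 0), (0, 0)])
        with pytest.raises(ValueError, match="zero path length"):
            directional_displacement_ratio(t, 20)

    def test_signed_numerator_can_be_negative(self):
        t = straight_track(10, (0, -1))
        assert directional_displacement_ratio(t, 50) == pytest.approx(-1.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_ordering_invariants_random_walks(self, seed):
        """|d_y/D| <= d/D <= 1 and max(vx, vy) <= v <= vx + vy on any track."""
        rng = np.random.default_rng(seed)
        t = make_track(np.cumsum(rng.normal(scale=2.0, size=(30, 2)), axis=0))
        v = average_speed(t)
        sp = directional_speeds(t)
        assert max(sp.v_x_um_per_min, sp.v_y_um_per_min) <= v + 1e-12
        assert v <= sp.v_x_um_per_min + sp.v_y_um_per_min + 1e-12
        for delta in (10, 50, 140, 290):
            dy = directional_displacement_ratio(t, delta)
            dd = directionality_ratio(t, delta)
            assert abs(dy) <= dd + 1e-12 <= 1 + 1e-12


class TestCohortCurve:
    def test_straight_cohort(self):
        tracks = [straight_track(60, (0, 1), cell_id=f"c{i}") for i in range(5)]
        curve = cohort_ratio_curve(tracks, [10, 100, 600])
        assert np.allclose(curve["mean"], 1.0) and np.allclose(curve["sem"], 0.0)

    def test_single_track_sem_zero(self):
        curve = cohort_ratio_curve([straight_track(10, (0, 1))], [50])
        assert curve["sem"].iloc[0] == 0.0 and curve["n"].iloc[0] == 1

    def test_isotropic_cohort_signed_mean_near_zero(self):
        tracks = simulate_trajectories(SimulationParams(n_cells=500, persistence=0.0, seed=13), CONTROL)
        curve = cohort_ratio_curve(tracks, [600])
        assert abs(curve["mean"].iloc[0]) < 0.03

    def test_short_tracks_drop_out(self):
        tracks = [straight_track(5, (0, 1), cell_id="short"), straight_track(20, (0, 1), cell_id="long")]
        curve = cohort_ratio_curve(tracks, [100])
        assert curve["n"].iloc[0] == 1

    def test_ratio_curve_nonincreasing_for_fixed_speed_walk(self):
        tracks = simulate_trajectories(
            SimulationParams(n_cells=400, persistence=0.5, axis_bias=3.0, speed_sd=0.0, seed=14),
            GD725,
        )
        curve = cohort_ratio_curve(tracks, [10, 50, 100, 300, 600], signed=False)
        means = curve["mean"].to_numpy()
        assert np.all(np.diff(means) <= 0.02)  # stochastic tolerance


class TestMsdVacf:
    def test_straight_line_msd_quadratic(self):
        t = straight_track(30, (0, 2))  # 0.2 um/min
        msd = mean_squared_displacement([t], [10, 50, 100])
        assert np.allclose(msd["msd_um2"], (0.2 * msd["lag_min"]) ** 2)

    def test_stationary_msd_zero(self):
        t = make_track(np.zeros((20, 2)))
        assert np.allclose(mean_squared_displacement([t], [10, 50])["msd_um2"], 0.0)

    def test_isotropic_walk_msd_linear(self):
        tracks = simulate_trajectories(
            SimulationParams(n_cells=500, persistence=0.0, speed_sd=0.0, seed=15), CONTROL
        )
        msd = mean_squared_displacement(tracks, [10, 20, 40])
        step_sq = msd["msd_um2"].iloc[0]
        assert msd["msd_um2"].iloc[1] == pytest.approx(2 * step_sq, rel=0.05)
        assert msd["msd_um2"].iloc[2] == pytest.approx(4 * step_sq, rel=0.05)

    def test_lag_exceeding_all_tracks_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            mean_squared_displacement([straight_track(5, (0, 1))], [100])

    def test_straight_line_vacf_one(self):
        t = straight_track(30, (0, 1))
        v = velocity_autocorrelation([t], [0, 10, 50])
        assert np.allclose(v["vacf"], 1.0)

    def test_isotropic_nonpersistent_vacf_zero(self):
        tracks = simulate_trajectories(SimulationParams(n_cells=500, persistence=0.0, seed=16), CONTROL)
        v = velocity_autocorrelation(tracks, [10])
        assert abs(v["vacf"].iloc[0]) < 0.05

    @pytest.mark.parametrize("p", [0.3, 0.7, 0.9])
    def test_vacf_recovers_persistence(self, p):
        tracks = simulate_trajectories(
            SimulationParams(n_cells=300, persistence=p, axis_bias=0.0, seed=17), CONTROL
        )
        v = velocity_autocorrelation(tracks, [10])
        assert v["vacf"].iloc[0] == pytest.approx(p, abs=0.05)


def test_parameter_recovery_orientation_and_speed_ratio():
    """Across a bias grid, mean orientation strictly falls and v_y/v_x strictly rises."""
    orientations, ratios = [], []
    for bias in (0.0, 1.0, 3.0, 8.0, 20.0):
        tracks = simulate_trajectories(SimulationParams(n_cells=300, axis_bias=bias, seed=18), GD725)
        orientations.append(np.mean([directional_orientation(t) for t in tracks]))
        sp = [directional_speeds(t) for t in tracks]
        ratios.append(np.mean([s.v_y_um_per_min for s in sp]) / np.mean([s.v_x_um_per_min for s in sp]))
    assert all(a > b for a, b in zip(orientations, orientations[1:]))
    assert all(a < b for a, b in zip(ratios, ratios[1:]))
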