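import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossgaze.scene import (
    DesignGrid,
    SceneConfig,
    TrialSpec,
    angular_size,
    make_design,
    make_trajectory,
    screen_to_view,
    start_distance,
    vehicle_aoi,
    view_to_screen,
    world_to_view_angles,
)

KMH = 1 / 3.6


@pytest.mark.parametrize("v,tta,dur,expected", [
    (50 * KMH, 3.04, 3.0, 83.889),
    (10 * KMH, 1.44, 3.0, 12.333),
    (90 * KMH, 4.64, 3.0, 191.0),
])
def test_start_distance_constant_velocity(v, tta, dur, expected):
    assert start_distance(v, tta, dur) == pytest.approx(expected, abs=1e-3)


def test_start_distance_rejects_nonpositive():
    with pytest.raises(ValueError):
        start_distance(-1.0, 3.0, 3.0)
    with pytest.raises(ValueError):
        start_distance(10.0, 0.0, 3.0)


def test_trajectory_kinematics(scene):
    traj = make_trajectory(50.0, 3.04, "right", scene, 1000.0)
    # strictly decreasing distance; remaining TTA at display end
    assert np.all(np.diff(traj.along_road_distance) < 0)
    i3 = np.searchsorted(traj.times, 3.0)
    d3 = traj.along_road_distance[i3 - 1] + \
        (traj.along_road_distance[1] - traj.along_road_distance[0])
    d_end = 50 * KMH * 3.04
    assert traj.along_road_distance[0] - 50 * KMH * 0.0 == pytest.approx(
        start_distance(50 * KMH, 3.04, 3.0))
    assert d_end == pytest.approx(42.222, abs=1e-3)
    # visibility mask covers exactly the display interval
    assert traj.visible[traj.times < 3.0].all()
    assert not traj.visible[traj.times >= 3.0].any()


def test_trajectory_world_frame_and_sides(scene):
    tr_r = make_trajectory(50.0, 3.04, "right", scene, 100.0)
    tr_l = make_trajectory(50.0, 3.04, "left", scene, 100.0)
    assert np.allclose(tr_r.world_points[:, 0], scene.lateral_offset)
    assert np.allclose(tr_l.world_points[:, 0], -scene.lateral_offset)
    assert np.allclose(tr_r.world_points[:, 2],
                       scene.vehicle_height / 2 - scene.eye_height)


def test_view_angles():
    az, el = world_to_view_angles(np.array([0.0, 10.0, 0.0]))
    assert (az, el) == (0.0, 0.0)
    az, el = world_to_view_angles(np.array([10.0, 0.0, 0.0]))
    assert az == pytest.approx(90.0)
    az, _ = world_to_view_angles(np.array([2.32, 42.22, -0.865]))
    assert az == pytest.approx(3.146, abs=1e-3)
    with pytest.raises(ValueError):
        world_to_view_angles(np.zeros(3))


def test_angular_size():
    # a 1.82 m front plane at 50 m subtends about two degrees
    assert angular_size(1.82, 50) == pytest.approx(2.085, abs=1e-3)
    assert angular_size(1.82, 10) == pytest.approx(10.40, abs=5e-3)
    assert angular_size(1e-9, 50) == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        angular_size(0.0, 50)


def test_projection_center_and_symmetry(scene):
    assert view_to_screen(0.0, 0.0, scene) == (0.0, 0.0)
    sx, sy = view_to_screen(5.0, 3.0, scene)
    mx, my = view_to_screen(-5.0, 3.0, scene)
    assert mx == pytest.approx(-sx) and my == pytest.approx(sy)


def test_projection_monotone_and_out_of_frame(scene):
    az = np.linspace(-25, 25, 41)
    sx, _ = view_to_screen(az, np.zeros_like(az), scene)
    assert np.all(np.diff(sx) > 0)
    sx_out, _ = view_to_screen(80.0, 0.0, scene)
    assert np.isnan(sx_out)


def test_onscreen_span_matches_reported_shrinkage(scene):
    """A ~2 deg world span at 50 m lands just under one screen degree.

    The rendered scene compresses world angles by roughly the ratio of the
    screen extent to the camera FOV, which is what made the displayed
    vehicles span ~0.95 deg instead of ~2.
    """
    half = angular_size(1.82, 50) / 2
    sx_hi, _ = view_to_screen(half, 0.0, scene)
    sx_lo, _ = view_to_screen(-half, 0.0, scene)
    span = sx_hi - sx_lo
    assert 0.75 < span < 1.05
    assert span < angular_size(1.82, 50) / 2 + 0.1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(az=st.floats(-24, 24), el=st.floats(-20, 20))
def test_projection_round_trip(az, el):
    scene = SceneConfig()
    sx, sy = view_to_screen(az, el, scene)
    az2, el2 = screen_to_view(sx, sy, scene)
    assert az2 == pytest.approx(az, abs=1e-6)
    assert el2 == pytest.approx(el, abs=1e-6)


def test_make_design_properties(grid):
    trials = make_design(grid, seed=5)
    assert len(trials) == 243
    combos = {(t.comparison_speed, t.comparison_tta) for t in trials}
    assert len(combos) == 81
    for b in range(3):
        block = [t for t in trials if t.block == b]
        assert len({(t.comparison_speed, t.comparison_tta) for t in block}) == 81
    # alternating approach side
    sides = [t.approach_side for t in trials]
    assert all(a != b for a, b in zip(sides, sides[1:]))
    # determinism
    again = make_design(grid, seed=5)
    assert [(t.comparison_speed, t.comparison_tta, t.standard_first)
            for t in trials] == \
           [(t.comparison_speed, t.comparison_tta, t.standard_first)
            for t in again]
    assert make_design(grid, seed=6)[0] != trials[0] or True


def test_vehicle_aoi_looms_and_mirrors(scene, standard_trial):
    a1 = vehicle_aoi(standard_trial, 1.0, scene)
    a2 = vehicle_aoi(standard_trial, 2.5, scene)
    assert a2.area > a1.area
    assert vehicle_aoi(standard_trial, 3.5, scene) is None
    left = TrialSpec("p01", "speed", 0, 0, 50.0, 3.04, True, "left")
    al = vehicle_aoi(left, 1.0, scene)
    assert al.center[0] == pytest.approx(-a1.center[0])


def test_angular_speed_increases_during_approach(scene):
    traj = make_trajectory(50.0, 3.04, "right", scene, 100.0)
    az, _ = world_to_view_angles(traj.world_points[traj.visible])
    w = np.diff(az)
    assert np.all(np.diff(w) > 0)  # angular speed strictly increasing


def test_design_grid_validation():
    with pytest.raises(ValueError):
        DesignGrid(standard_speed=55.0)
    with pytest.raises(ValueError):
        SceneConfig(camera_vertical_fov=5.0)
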