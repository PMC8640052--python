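import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossgaze.metrics import (
    MetricsConfig,
    OutlierConfig,
    angular_velocity_3d,
    mad_outlier_filter,
    position_deviation,
    pursuit_gain,
    saccade_stats,
)
from crossgaze.preprocess import EventLabels
from crossgaze.scene import AoiBox, view_angles_to_unit


def test_angular_velocity_constant_rotation():
    # 0.005 deg per 1 ms sample -> 5 deg/s
    az = np.arange(1000) * 0.005
    dirs = view_angles_to_unit(az, np.zeros_like(az))
    w = angular_velocity_3d(dirs, 0.001)
    assert np.allclose(w, 5.0, atol=1e-6)


def test_angular_velocity_static_zero():
    dirs = np.tile(view_angles_to_unit(3.0, 1.0), (100, 1))
    assert np.allclose(angular_velocity_3d(dirs, 0.001), 0.0)


def test_angular_velocity_rejects_zero_vector():
    dirs = np.zeros((10, 3))
    with pytest.raises(ValueError):
        angular_velocity_3d(dirs, 0.001)


def test_angular_velocity_matches_planar_small_angles():
    # at eccentricities < 5 deg the 3D measure agrees with the planar 2D
    # speed to within 0.1%
    rng = np.random.default_rng(0)
    az = np.cumsum(rng.normal(0.002, 0.0005, 2000)) + 1.0
    el = np.full_like(az, 0.0)
    az = np.clip(az, None, 5.0)
    el = np.cumsum(rng.normal(0.001, 0.0003, 2000))
    dirs = view_angles_to_unit(az, el)
    w3 = angular_velocity_3d(dirs, 0.001)
    w2 = np.hypot(np.diff(az), np.diff(el)) / 0.001  # planar approximation
    sel = w2 > 0.1
    assert np.allclose(w3[sel], w2[sel], rtol=1e-3)


def test_pursuit_gain_trivial_cases(scene, standard_traj):
    from crossgaze.observer import GazeTrace
    from crossgaze.scene import aoi_center_path

    tgt = aoi_center_path(standard_traj, scene)
    t_ms = standard_traj.times * 1000.0
    tracking = GazeTrace(0, "comparison", t_ms, tgt[:, 0], tgt[:, 1],
                         np.ones(len(t_ms), bool))
    assert pursuit_gain(tracking, standard_traj, scene=scene) == \
        pytest.approx(1.0, abs=0.01)
    static = GazeTrace(0, "comparison", t_ms, np.zeros(len(t_ms)),
                       np.zeros(len(t_ms)), np.ones(len(t_ms), bool))
    assert pursuit_gain(static, standard_traj, scene=scene) == \
        pytest.approx(0.0, abs=0.01)


def test_position_deviation_cases():
    from crossgaze.observer import GazeTrace

    n = 3000
    t_ms = np.arange(n, dtype=float)
    centers = np.zeros((n, 2))
    on_target = GazeTrace(0, "c", t_ms, np.zeros(n), np.zeros(n),
                          np.ones(n, bool))
    assert position_deviation(on_target, centers, (0, 3)) == (0, 0, 0, 0)

    above = GazeTrace(0, "c", t_ms, np.zeros(n), np.full(n, 0.5),
                      np.ones(n, bool))
    rel_h, rel_v, abs_h, abs_v = position_deviation(above, centers, (0, 3))
    assert rel_v == abs_v == pytest.approx(0.5)

    jitter = GazeTrace(0, "c", t_ms, np.where(np.arange(n) % 2, 1.0, -1.0),
                       np.zeros(n), np.ones(n, bool))
    rel_h, _, abs_h, _ = position_deviation(jitter, centers, (0, 3))
    assert abs(rel_h) < 0.01 and abs_h == pytest.approx(1.0)

    # left-approach trials flip the horizontal sign: +x lag becomes "behind"
    lag = GazeTrace(0, "c", t_ms, np.full(n, 0.3), np.zeros(n),
                    np.ones(n, bool))
    rh_right, *_ = position_deviation(lag, centers, (0, 3), "right")
    rh_left, *_ = position_deviation(lag, centers, (0, 3), "left")
    assert rh_right == pytest.approx(0.3) and rh_left == pytest.approx(-0.3)

    with pytest.raises(ValueError):
        position_deviation(on_target, centers, (5, 6))


def test_saccade_stats_first_removed_and_crossing_split():
    crossing = AoiBox(center=(0.0, -6.0), half_width=10.0, half_height=5.0,
                      kind="crossing")
    one = EventLabels(saccades=[(100.0, 130.0, 2.0, 0.0)])
    s = saccade_stats(one, crossing, 3.0)
    assert s["n_saccades"] == 0 and np.isnan(s["mean_amplitude"])

    three = EventLabels(saccades=[(100.0, 130.0, 1.0, 0.0),
                                  (500.0, 530.0, 2.0, 0.0),
                                  (900.0, 930.0, 3.0, 0.0)])
    s = saccade_stats(three, crossing, 3.0)
    assert s["n_saccades"] == 2 and s["mean_amplitude"] == pytest.approx(2.5)

    # a saccade landing in the crossing AOI after 3 s counts as "after"
    from crossgaze.observer import GazeTrace
    n = 5000
    t_ms = np.arange(n, dtype=float)
    y = np.zeros(n)
    y[3500:] = -6.0  # gaze sits inside the crossing box
    tr = GazeTrace(0, "c", t_ms, np.zeros(n), y, np.ones(n, bool))
    ev = EventLabels(saccades=[(100.0, 130.0, 1.0, 0.0),
                               (3470.0, 3500.0, 6.0, -90.0)])
    s = saccade_stats(ev, crossing, 3.0, trace=tr)
    assert s["n_sacc_crossing_after"] == 1
    assert s["n_sacc_crossing_before"] == 0


def brute_force_double_mad(x, cutoff=4.5, c=1.4826):
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    lo = x[x <= med] - med
    hi = x[x >= med] - med
    mad_lo = np.median(np.abs(lo - np.median(lo) * 0)) if len(lo) else 0.0
    mad_lo = np.median(np.abs(lo))
    mad_hi = np.median(np.abs(hi))
    keep = np.ones(len(x), bool)
    for i, v in enumerate(x):
        if v < med and mad_lo > 0 and abs(v - med) / (c * mad_lo) > cutoff:
            keep[i] = False
        if v > med and mad_hi > 0 and abs(v - med) / (c * mad_hi) > cutoff:
            keep[i] = False
    return keep


def test_symmetric_mad_flags_gross_outlier():
    vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
    keep = mad_outlier_filter(vals)
    assert not keep[-1] and keep[:-1].all()
    # score of the outlier is about 25.5 with the consistency constant
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    assert abs(100 - med) / (1.4826 * mad) == pytest.approx(25.6, abs=0.5)


def test_mad_constant_vector_guard():
    with pytest.warns(UserWarning):
        keep = mad_outlier_filter(np.ones(10))
    assert keep.all()


def test_mad_scale_invariance():
    rng = np.random.default_rng(5)
    x = rng.gamma(2.0, 1.0, 200)
    k1 = mad_outlier_filter(x, asymmetric=True)
    k2 = mad_outlier_filter(x * 37.5, asymmetric=True)
    assert np.array_equal(k1, k2)


def test_symmetric_mad_false_positive_rate():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 10_000)
    keep = mad_outlier_filter(x)
    assert (~keep).mean() < 0.002


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=20),
       st.integers(0, 2**16))
def test_double_mad_matches_brute_force(values, salt):
    x = np.asarray(values) + salt * 0.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        keep = mad_outlier_filter(x, asymmetric=True)
    assert np.array_equal(keep, brute_force_double_mad(x))
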