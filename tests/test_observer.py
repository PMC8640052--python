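import numpy as np
import pytest
from scipy import stats

from crossgaze.metrics import pursuit_gain
from crossgaze.observer import (
    ObserverParams,
    cue_zscores,
    default_participants,
    generate_dataset,
    internal_estimate,
    simulate_gaze,
    simulate_response,
)
from crossgaze.scene import DesignGrid, aoi_center_path


def _quiet(**kw):
    base = dict(pursuit_gain_sd=0.0, fixation_noise_sd=0.0,
                saccade_rate_bias=0.0, blink_rate=0.0,
                saccade_amplitude_noise_sd=0.0,
                anchor_offset_mean=(0.0, 0.0), anchor_offset_sd=(0.0, 0.0))
    base.update(kw)
    return ObserverParams(**base)


def test_perfect_tracker_reproduces_target(scene, standard_trial, standard_traj):
    p = _quiet(pursuit_gain_mean=1.0, catchup_threshold=np.inf)
    tr = simulate_gaze(standard_trial, standard_traj, p, seed=0, scene=scene)
    tgt = aoi_center_path(standard_traj, scene)
    vis = standard_traj.visible
    assert np.allclose(tr.gaze_x[vis], tgt[vis, 0], atol=1e-9)
    assert np.allclose(tr.gaze_y[vis], tgt[vis, 1], atol=1e-9)


def test_low_gain_catchups_follow_motion(scene, standard_traj):
    from crossgaze.scene import TrialSpec

    # a lagging tracker on a long leftward-moving path accumulates error in
    # the motion direction; its catch-up saccades must point the same way
    trial = TrialSpec("p01", "speed", 0, 0, 10.0, 1.44, True, "left")
    from crossgaze.scene import make_trajectory
    traj = make_trajectory(10.0, 1.44, "left", scene, 1000.0)
    p = _quiet(pursuit_gain_mean=0.7, catchup_threshold=0.5)
    tr = simulate_gaze(trial, traj, p, seed=0, scene=scene)
    tgt = aoi_center_path(traj, scene)
    vis = traj.visible
    motion = tgt[vis][-1, 0] - tgt[vis][0, 0]
    assert len(tr.truth.saccades) >= 1
    for _on, _off, _amp, direction in tr.truth.saccades:
        assert np.cos(np.radians(direction)) * np.sign(motion) > 0


def test_gaze_determinism(scene, standard_trial, standard_traj):
    p = ObserverParams()
    a = simulate_gaze(standard_trial, standard_traj, p, seed=7, scene=scene)
    b = simulate_gaze(standard_trial, standard_traj, p, seed=7, scene=scene)
    assert np.array_equal(a.gaze_x, b.gaze_x)
    assert np.array_equal(a.pupil_valid, b.pupil_valid)
    c = simulate_gaze(standard_trial, standard_traj, p, seed=8, scene=scene)
    assert not np.array_equal(a.gaze_x, c.gaze_x)


@pytest.mark.parametrize("g", [0.5, 0.8, 1.1])
def test_measured_gain_matches_generative(g, scene, standard_trial, standard_traj):
    p = _quiet(pursuit_gain_mean=g, catchup_threshold=np.inf)
    tr = simulate_gaze(standard_trial, standard_traj, p, seed=1, scene=scene)
    assert pursuit_gain(tr, standard_traj, scene=scene) == pytest.approx(g, abs=0.02)


def test_internal_estimate_deterministic_ordering(grid):
    rng = np.random.default_rng(0)
    w = {"speed": 1.0}
    z60 = cue_zscores(60.0, 3.04, grid)
    z50 = cue_zscores(50.0, 3.04, grid)
    assert internal_estimate(z60, w, 0.0, rng) > internal_estimate(z50, w, 0.0, rng)


def test_differencing_rule_matches_gaussian_oracle(grid):
    """P(correct) for the 2IFC differencing rule equals Phi(delta/(sigma*sqrt(2))).

    Monte-Carlo oracle: sigma = 10, delta = 10 gives 0.760.
    """
    rng = np.random.default_rng(123)
    n = 200_000
    a = 10.0 + rng.normal(0, 10.0, n)
    b = 0.0 + rng.normal(0, 10.0, n)
    mc = float(np.mean(a > b))
    closed = stats.norm.cdf(10.0 / (10.0 * np.sqrt(2)))
    assert closed == pytest.approx(0.760, abs=0.001)
    assert mc == pytest.approx(closed, abs=0.005)


def test_response_rules(grid):
    from crossgaze.scene import TrialSpec

    # deterministic "earlier" rule: TTA 1.44 beats the 3.04 standard
    p = _quiet(cue_weights={"speed": {"speed": 1.0}, "tta": {"tta": -1.0}},
               internal_noise_sd=0.0, lapse_prob=0.0, second_interval_bias=0.0)
    trial = TrialSpec("p01", "tta", 0, 0, 50.0, 1.44, True, "right")
    for seed in range(5):
        assert simulate_response(trial, p, seed=seed, grid=grid)["chose_comparison"]

    # pure guessing: lapse 1 gives ~50% correct on decidable trials
    p_guess = _quiet(lapse_prob=1.0)
    trial2 = TrialSpec("p01", "speed", 0, 0, 90.0, 3.04, True, "right")
    correct = [simulate_response(trial2, p_guess, seed=s, grid=grid)["correct"]
               for s in range(400)]
    assert 0.4 < np.mean(correct) < 0.6

    # positive second-interval bias on identical stimuli
    p_bias = _quiet(internal_noise_sd=1.0, lapse_prob=0.0,
                    second_interval_bias=1.0)
    tie = TrialSpec("p01", "speed", 0, 0, 50.0, 3.04, True, "right")
    chose2 = [simulate_response(tie, p_bias, seed=s, grid=grid)["choice"] == 2
              for s in range(400)]
    assert np.mean(chose2) > 0.6


def test_identical_stimuli_balanced_without_bias(grid):
    from crossgaze.scene import TrialSpec

    p = _quiet(internal_noise_sd=1.0, lapse_prob=0.0, second_interval_bias=0.0)
    tie = TrialSpec("p01", "speed", 0, 0, 50.0, 3.04, False, "right")
    chose2 = [simulate_response(tie, p, seed=s, grid=grid)["choice"] == 2
              for s in range(600)]
    assert np.mean(chose2) == pytest.approx(0.5, abs=0.07)


def test_generate_dataset_shape_and_roundtrip(tmp_path, scene, grid):
    from crossgaze import io as cio

    parts = default_participants(2, seed=3)
    ds = generate_dataset(parts, seed=4, scene=scene, grid=grid,
                          gaze_sample_rate=100.0, n_blocks=1)
    assert len(ds["trials"]) == 2 * 2 * 81
    assert len(ds["traces"]) == 2 * len(ds["trials"])
    cio.write_trials(ds["trials"], tmp_path / "trials.tsv")
    back = cio.read_trials(tmp_path / "trials.tsv")
    assert back[["participant_id", "task", "trial_index"]].equals(
        ds["trials"][["participant_id", "task", "trial_index"]])
    cio.write_traces(ds["traces"], tmp_path / "gaze")
    traces = cio.read_traces(tmp_path / "gaze")
    key = next(iter(ds["traces"]))
    orig, rt = ds["traces"][key], traces[key]
    assert np.allclose(orig.gaze_x, rt.gaze_x, atol=1e-4)
    assert np.array_equal(orig.pupil_valid, rt.pupil_valid)


def test_psychometric_slope_consistent_with_internal_noise(grid):
    """Responses from weights {speed: 1}, noise sigma fit with slope ~ sigma*sqrt(2).

    The differencing rule on two noisy estimates doubles the variance, so
    the psychometric sigma in z-units is sigma*sqrt(2) (checked within 5%).
    """
    from crossgaze.psychometrics import fit_psychometric

    sigma_z = 0.5
    p = _quiet(cue_weights={"speed": {"speed": 1.0}, "tta": {"tta": -1.0}},
               internal_noise_sd=sigma_z, lapse_prob=0.0,
               second_interval_bias=0.0)
    rng = np.random.default_rng(99)
    speeds = np.array(grid.speed_levels)
    n_per = 3000
    k = np.zeros(9)
    from crossgaze.scene import TrialSpec
    sd_speed = np.std([c[0] for c in grid.cells])
    for i, sp in enumerate(speeds):
        trial = TrialSpec("p01", "speed", 0, 0, float(sp), 3.04, True, "right")
        k[i] = sum(simulate_response(trial, p, seed=int(rng.integers(2**31)),
                                     grid=grid)["chose_comparison"]
                   for _ in range(n_per))
    fit = fit_psychometric(speeds, k, np.full(9, n_per),
                           gamma_bounds=(0, 1e-6), lambda_bounds=(0, 1e-6))
    expected = sigma_z * np.sqrt(2) * sd_speed
    assert fit.slope_sigma == pytest.approx(expected, rel=0.05)
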