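import numpy as np
import pandas as pd
import pytest

from crossgaze.dominance import (
    TheoreticalObserverSpec,
    fit_cue_logistic,
    general_dominance,
    theoretical_observer_responses,
    trial_cue_matrix,
)
from crossgaze.scene import DesignGrid, make_design


def _trial_frame(grid, n_rep=3, seed=0):
    rows = []
    for rep in range(n_rep):
        for t in make_design(grid, seed=seed + rep):
            rows.append({"comparison_speed": t.comparison_speed,
                         "comparison_tta": t.comparison_tta})
    return pd.DataFrame(rows)


def test_null_choices_give_null_model(grid):
    rng = np.random.default_rng(0)
    df = _trial_frame(grid)
    X = trial_cue_matrix(df, grid)
    y = rng.random(len(df)) < 0.5
    res = fit_cue_logistic(y, X)
    assert abs(res["r2m"]) < 0.02
    # coefficients are individually noisy (the cues covary strongly) but
    # must stay far from any real effect size
    assert all(abs(v) < 0.4 for k, v in res["coefficients"].items()
               if k != "intercept")


def test_deterministic_speed_threshold_dominated_by_speed(grid):
    df = _trial_frame(grid)
    X = trial_cue_matrix(df, grid)
    y = (df["comparison_speed"] > 50).to_numpy()
    res = general_dominance(y, X)
    gd = res.general_dominance
    assert gd["speed"] == max(gd.values())
    assert res.r2m_full > 0.5


def test_dominance_additivity_and_single_predictor(grid):
    rng = np.random.default_rng(1)
    df = _trial_frame(grid)
    X = trial_cue_matrix(df, grid)
    logit = 0.8 * X["speed"] - 0.5 * X["tta"]
    y = rng.random(len(df)) < 1 / (1 + np.exp(-logit))
    res = general_dominance(y, X)
    assert sum(res.general_dominance.values()) == \
        pytest.approx(res.r2m_full, abs=1e-10)
    # single predictor: GD equals the sole-model R2
    res1 = general_dominance(y, X[["speed", "tta"]])
    sole = 1 - fit_cue_logistic(y, X[["speed"]])["loglik"] / \
        fit_cue_logistic(y, X[["speed"]])["loglik_null"]
    # two-predictor GD for speed is bounded by its sole-model R2 pattern;
    # exact equality holds for p = 1
    single = general_dominance(y, X[["speed", "tta"]])
    assert single.subset_r2m[("speed",)] == pytest.approx(sole, abs=1e-9)


def test_orthogonal_predictors_gd_equals_sole_r2():
    rng = np.random.default_rng(2)
    n = 4000
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    X = (X - X.mean()) / X.std(ddof=0)
    y = rng.random(n) < 1 / (1 + np.exp(-(0.9 * X["a"] + 0.5 * X["b"])))
    res = general_dominance(y, X)
    for col in ("a", "b"):
        assert res.general_dominance[col] == \
            pytest.approx(res.subset_r2m[(col,)], abs=0.01)


def test_gd_invariant_to_predictor_scaling(grid):
    rng = np.random.default_rng(3)
    df = _trial_frame(grid)
    X = trial_cue_matrix(df, grid)
    y = rng.random(len(df)) < 1 / (1 + np.exp(-X["speed"]))
    g1 = general_dominance(y, X).general_dominance
    g2 = general_dominance(y, X * 11.0).general_dominance
    for k in g1:
        assert g1[k] == pytest.approx(g2[k], abs=1e-6)


def test_theoretical_observer_noise_free_is_perfect(grid):
    df = _trial_frame(grid, n_rep=1)
    spec = TheoreticalObserverSpec("faster-if-speed-greater", 0.0, seed=0)
    choices = theoretical_observer_responses(df, spec, grid)
    truth = df["comparison_speed"] > grid.standard_speed
    decidable = df["comparison_speed"] != grid.standard_speed
    assert np.array_equal(choices[decidable.to_numpy()],
                          truth[decidable].to_numpy())


def test_theoretical_observer_tie_symmetry(grid):
    df = pd.DataFrame({"comparison_speed": [50.0] * 4000,
                       "comparison_tta": [3.04] * 4000})
    spec = TheoreticalObserverSpec("faster-if-speed-greater", 5.0, seed=1)
    choices = theoretical_observer_responses(df, spec, grid)
    assert np.mean(choices) == pytest.approx(0.5, abs=0.03)


def test_theoretical_observer_loads_on_task_cue(grid):
    df = _trial_frame(grid, n_rep=3)
    spec = TheoreticalObserverSpec("earlier-if-tta-smaller", 0.7, seed=2)
    choices = theoretical_observer_responses(df, spec, grid)
    res = general_dominance(choices, trial_cue_matrix(df, grid))
    gd = res.general_dominance
    assert gd["tta"] == max(gd.values())
    # residual loading on distance cues reflects grid covariation only
    assert gd["tta"] > 2 * gd["speed"]


def test_distance_weighted_observer_shifts_dominance_from_tta(grid):
    """Observers who overweight position cues show the signature dominance
    pattern: more start/end-distance dominance and less TTA dominance than
    a noise-matched single-cue observer."""
    from crossgaze.observer import ObserverParams, simulate_response
    from crossgaze.psychometrics import fit_from_trials

    p = ObserverParams(internal_noise_sd=0.5, lapse_prob=0.0,
                       second_interval_bias=0.0)
    rng = np.random.default_rng(4)
    rows = []
    for rep in range(4):
        for t in make_design(grid, seed=40 + rep, task="tta"):
            r = simulate_response(t, p, seed=int(rng.integers(2**31)), grid=grid)
            rows.append({"task": "tta", "comparison_speed": t.comparison_speed,
                         "comparison_tta": t.comparison_tta,
                         "standard_first": t.standard_first, **r})
    df = pd.DataFrame(rows)
    part = general_dominance(df["chose_comparison"].to_numpy(dtype=bool),
                             trial_cue_matrix(df, grid))
    fit = fit_from_trials(df, "tta", grid.standard_tta)
    theo_spec = TheoreticalObserverSpec("earlier-if-tta-smaller",
                                        fit.slope_sigma / np.sqrt(2), seed=5)
    theo_choices = theoretical_observer_responses(df, theo_spec, grid)
    theo = general_dominance(theo_choices, trial_cue_matrix(df, grid))
    assert part.general_dominance["tta"] < theo.general_dominance["tta"]
    assert part.general_dominance["end"] > theo.general_dominance["end"]
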