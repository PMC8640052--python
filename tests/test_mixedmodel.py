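import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from crossgaze.mixedmodel import (
    MixedModelSpec,
    fit_mixed_logistic,
    simplify_ladder,
    vif,
)

FIXED = ["gain", "n_saccades", "mean_amplitude", "rel_dev_h", "rel_dev_v",
         "abs_dev_h", "abs_dev_v"]


def simulate_glmm_data(seed, n_obs=10, n_trials=200, b_nsacc=-0.35,
                       b_amp=0.5, sd_obs=0.5, sd_speed=0.3, sd_tta=0.3):
    rng = np.random.default_rng(seed)
    obs_int = rng.normal(0, sd_obs, n_obs)
    sp_int = rng.normal(0, sd_speed, 9)
    tt_int = rng.normal(0, sd_tta, 9)
    rows = []
    for i in range(n_obs):
        for _ in range(n_trials):
            nsac = rng.poisson(3)
            amp = rng.gamma(9, 0.12)
            sp = int(rng.integers(9))
            tt = int(rng.integers(9))
            eta = (1.2 + obs_int[i] + sp_int[sp] + tt_int[tt]
                   + b_nsacc * (nsac - 3) / np.sqrt(3)
                   + b_amp * (amp - 1.08) / 0.36)
            rows.append({
                "participant_id": f"p{i}", "comparison_speed": sp,
                "comparison_tta": tt, "gain": rng.normal(0.87, 0.12),
                "n_saccades": nsac, "mean_amplitude": amp,
                "rel_dev_h": rng.normal(0.5, 0.3),
                "rel_dev_v": rng.normal(0.7, 0.4),
                "abs_dev_h": abs(rng.normal(1.3, 0.4)),
                "abs_dev_v": abs(rng.normal(0.95, 0.3)),
                "correct": int(rng.random() < 1 / (1 + np.exp(-eta)))})
    return pd.DataFrame(rows)


def test_vif_orthogonal_and_collinear():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
    vals = vif(X)
    assert all(1.0 <= v < 1.1 for v in vals.values())
    X["d"] = X["a"] + rng.normal(0, 0.01, 500)
    vals = vif(X)
    assert vals["d"] > 10 and vals["a"] > 10

    X["e"] = X["b"] * 2.0
    with pytest.raises(ValueError, match="aliased"):
        vif(X)


def test_fixed_effect_recovery_and_uncertainty():
    df = simulate_glmm_data(seed=1)
    rep = fit_mixed_logistic(df, MixedModelSpec())
    est = rep.estimates.set_index("term")
    assert est.loc["n_saccades", "estimate"] == pytest.approx(-0.35, abs=0.12)
    assert est.loc["mean_amplitude", "estimate"] == pytest.approx(0.5, abs=0.15)
    assert est.loc["n_saccades", "p"] < 0.001
    # null covariates stay null
    assert abs(est.loc["rel_dev_v", "estimate"]) < 0.15
    assert rep.converged
    assert all(v >= 1.0 for v in rep.vif.values())


def test_matches_lme4_reference_fit(tmp_path):
    """Cross-check the Laplace fit against glmer (nAGQ=1) on one dataset."""
    df = simulate_glmm_data(seed=2, n_obs=8, n_trials=150)
    rep = fit_mixed_logistic(df, MixedModelSpec())
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        for (c in c({', '.join(repr(f) for f in FIXED)}))
          d[[c]] <- scale(d[[c]])
        m <- glmer(correct ~ {' + '.join(FIXED)} + (1|participant_id) +
                   (1|comparison_speed) + (1|comparison_tta),
                   data=d, family=binomial, nAGQ=1)
        co <- summary(m)$coefficients
        cat(jsonlite::toJSON(list(est=unname(co[,1]), se=unname(co[,2]),
                                  ll=as.numeric(logLik(m)))))
    """)
    rfile = tmp_path / "check.R"
    rfile.write_text(rscript)
    out = subprocess.run(["Rscript", str(rfile)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    est = rep.estimates["estimate"].to_numpy()
    se = rep.estimates["se"].to_numpy()
    assert np.allclose(est, ref["est"], atol=0.02)
    assert np.allclose(se, ref["se"], rtol=0.05, atol=0.005)
    assert rep.loglik == pytest.approx(ref["ll"][0], abs=0.5)


def test_zero_variance_collapses_to_plain_logistic():
    import statsmodels.api as sm

    df = simulate_glmm_data(seed=3, sd_obs=0.0, sd_speed=0.0, sd_tta=0.0,
                            n_obs=6, n_trials=150)
    rep = fit_mixed_logistic(df, MixedModelSpec())
    X = (df[FIXED] - df[FIXED].mean()) / df[FIXED].std(ddof=0)
    design = np.column_stack([np.ones(len(df)), X.to_numpy()])
    plain = sm.Logit(df["correct"].to_numpy(float), design).fit(disp=0)
    assert np.allclose(rep.estimates["estimate"], plain.params, atol=0.03)
    assert all(v < 0.02 for v in rep.random_variances.values())


def test_loglik_invariant_to_row_and_level_order():
    df = simulate_glmm_data(seed=4, n_obs=6, n_trials=100)
    rep1 = fit_mixed_logistic(df, MixedModelSpec())
    shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    rep2 = fit_mixed_logistic(shuffled, MixedModelSpec())
    assert rep1.loglik == pytest.approx(rep2.loglik, abs=1e-3)
    a = rep1.estimates.sort_values("term")["estimate"].to_numpy()
    b = rep2.estimates.sort_values("term")["estimate"].to_numpy()
    assert np.allclose(a, b, atol=1e-3)


def test_ladder_with_slopes_and_records():
    df = simulate_glmm_data(seed=5, n_obs=8, n_trials=120)
    spec = MixedModelSpec(random_slopes={
        "participant_id": ("n_saccades",)})
    rep = simplify_ladder(df, spec)
    assert rep.converged
    assert rep.ladder_record[0]["step"] == "full-uncorrelated"
    converged_steps = [r for r in rep.ladder_record if r.get("converged")]
    assert converged_steps
    assert all("aic" in r for r in converged_steps)


def test_ladder_degenerate_single_observer_falls_back():
    df = simulate_glmm_data(seed=6, n_obs=1, n_trials=200)
    rep = simplify_ladder(df, MixedModelSpec())
    # one participant level cannot support a random factor; the ladder must
    # surface a usable (flagged) fit rather than crash
    assert rep.estimates is not None
    assert (not rep.converged) or rep.flags
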