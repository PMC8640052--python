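"""Cue use: per-participant logistic regression and general dominance.

Choices ("faster"/"earlier") are regressed on the four stimulus cues
(vehicle speed, time-to-arrival, start and end distance).  Because the
experimental grid forces start/end distance to covary with speed and TTA,
raw coefficients are hard to compare; general dominance instead averages
each predictor's incremental McFadden R^2 over all subset models (within
subset size first, then across sizes), a Shapley-value decomposition that
sums exactly to the full-model R^2.  A noisy single-cue theoretical
observer provides the baseline: any dominance it grants the other cues
reflects grid covariation alone, not strategy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .observer import cue_values
from .scene import DesignGrid

__all__ = [
    "CueDominanceResult",
    "TheoreticalObserverSpec",
    "fit_cue_logistic",
    "general_dominance",
    "theoretical_observer_responses",
    "trial_cue_matrix",
]

PREDICTORS = ("speed", "tta", "start", "end")


@dataclass
class CueDominanceResult:
    coefficients: dict
    r2m_full: float
    general_dominance: dict
    subset_r2m: dict
    flags: list


@dataclass(frozen=True)
class TheoreticalObserverSpec:
    rule: str  # "faster-if-speed-greater" | "earlier-if-tta-smaller"
    noise_sd: float  # stimulus units (from the participant's psychometric sigma)
    seed: int = 0
    noise_on_both_intervals: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rule not in ("faster-if-speed-greater", "earlier-if-tta-smaller"):
            raise ValueError("unknown rule")


def trial_cue_matrix(trials: pd.DataFrame, grid: DesignGrid | None = None,
                     display_duration: float = 3.0) -> pd.DataFrame:
    """Standardized comparison-interval cue matrix for the logistic fits."""
    cues = cue_values(trials["comparison_speed"].to_numpy(),
                      trials["comparison_tta"].to_numpy(), display_duration)
    X = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cues.items()})
    return (X - X.mean()) / X.std(ddof=0)


def _loglik_logistic(y: np.ndarray, X: np.ndarray | None):
    """Exact-MLE logistic log-likelihood; returns (llf, params, flag)."""
    n = len(y)
    design = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, design)
            res = model.fit(disp=0, maxiter=200)
            if np.any(~np.isfinite(res.params)) or np.any(np.abs(res.params) > 50):
                raise RuntimeError("divergent fit")
            return float(res.llf), np.asarray(res.params), None
        except Exception:
            # complete separation: small-ridge refit, flagged
            res = sm.Logit(y, design).fit_regularized(
                alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500)
            ll = float(sm.Logit(y, design).loglike(res.params))
            return ll, np.asarray(res.params), "separation-penalized"


def fit_cue_logistic(choices, predictors: pd.DataFrame) -> dict:
    """Full-model logistic fit with McFadden pseudo-R^2.

    ``choices`` is a boolean/0-1 vector; ``predictors`` must already be
    standardized.  R2_M = 1 - l_model / l_null.
    """
    y = np.asarray(choices, dtype=float)
    if len(y) < 50:
        raise ValueError("need at least 50 trials for a stable logistic fit")
    X = predictors.to_numpy(dtype=float)
    ll_null, _, _ = _loglik_logistic(y, None)
    ll, params, flag = _loglik_logistic(y, X)
    r2m = 1.0 - ll / ll_null
    coefs = {"intercept": float(params[0])}
    coefs.update({c: float(b) for c, b in zip(predictors.columns, params[1:])})
    return {"coefficients": coefs, "r2m": float(r2m), "loglik": ll,
            "loglik_null": ll_null, "flag": flag}


def general_dominance(choices, predictors: pd.DataFrame) -> CueDominanceResult:
    """General-dominance decomposition of the full-model McFadden R^2.

    For predictor j: average (within subset size, then across sizes 0..p-1)
    of the incremental R2_M from adding j to every subset excluding j,
    the empty set included.
    """
    y = np.asarray(choices, dtype=float)
    cols = list(predictors.columns)
    p = len(cols)
    if not (2 <= p <= 8):
        raise ValueError("dominance analysis supports 2-8 predictors")
    ll_null, _, _ = _loglik_logistic(y, None)
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    flags = []
    for size in range(1, p + 1):
        for S in itertools.combinations(cols, size):
            X = predictors[list(S)].to_numpy(dtype=float)
            ll, _, flag = _loglik_logistic(y, X)
            r2[frozenset(S)] = 1.0 - ll / ll_null
            if flag:
                flags.append(f"{flag}:{S}")
    gd = {}
    for j in cols:
        others = [c for c in cols if c != j]
        size_means = []
        for size in range(0, p):
            incs = [r2[frozenset(S) | {j}] - r2[frozenset(S)]
                    for S in itertools.combinations(others, size)]
            size_means.append(float(np.mean(incs)))
        gd[j] = float(np.mean(size_means))
    full = fit_cue_logistic(y, predictors)
    return CueDominanceResult(
        coefficients=full["coefficients"],
        r2m_full=r2[frozenset(cols)],
        general_dominance=gd,
        subset_r2m={tuple(sorted(k)): v for k, v in r2.items() if k},
        flags=flags,
    )


def theoretical_observer_responses(trials: pd.DataFrame,
                                   spec: TheoreticalObserverSpec,
                                   grid: DesignGrid | None = None) -> np.ndarray:
    """Choices of the noisy single-cue ideal observer.

    Gaussian noise (sd = the participant's fitted psychometric sigma, in
    stimulus units) is added to the task-relevant cue of each interval; the
    observer reports "faster" when the noised comparison speed exceeds the
    noised standard speed, or "earlier" when its noised TTA is smaller.
    Returns a boolean array: comparison chosen.
    """
    grid = grid or DesignGrid()
    rng = np.random.default_rng(spec.seed)
    n = len(trials)
    if spec.rule == "faster-if-speed-greater":
        cmp_val = trials["comparison_speed"].to_numpy(dtype=float)
        std_val = float(grid.standard_speed)
        larger_wins = True
    else:
        cmp_val = trials["comparison_tta"].to_numpy(dtype=float)
        std_val = float(grid.standard_tta)
        larger_wins = False
    noise_cmp = rng.normal(0.0, spec.noise_sd, n)
    noise_std = rng.normal(0.0, spec.noise_sd, n) \
        if spec.noise_on_both_intervals else np.zeros(n)
    a = cmp_val + noise_cmp
    b = std_val + noise_std
    chose_comparison = (a > b) if larger_wins else (a < b)
    ties = a == b
    if ties.any():
        chose_comparison = np.where(ties, rng.random(n) < 0.5, chose_comparison)
    return chose_comparison.astype(bool)


def participant_dominance(trials: pd.DataFrame, task: str,
                          grid: DesignGrid | None = None) -> CueDominanceResult:
    """Dominance analysis of one participant's responses in one task."""
    grid = grid or DesignGrid()
    df = trials[trials["task"] == task]
    X = trial_cue_matrix(df, grid)
    return general_dominance(df["chose_comparison"].to_numpy(dtype=bool), X)
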