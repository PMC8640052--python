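"""Psychometric fitting for 2IFC discrimination data.

Model: psi(x) = gamma + (1 - gamma - lambda) * Phi((x - pse) / sigma), fit
by maximizing the binomial log-likelihood with bounded parameters (guess
rate gamma in [0, 0.05], lapse rate lambda in [0, 0.1], PSE within the
stimulus range).  The JND is half the distance between the 25% and 75%
points of the full psi (asymptotes included); the Weber fraction divides it
by the standard stimulus.  Goodness of fit uses the deviance against the
saturated model with a parametric-bootstrap p value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PsychFit",
    "fit_psychometric",
    "jnd",
    "weber",
    "deviance_gof",
    "bootstrap_jnd",
    "interval_bias_fit",
]


@dataclass
class PsychFit:
    pse: float
    slope_sigma: float
    guess_gamma: float
    lapse_lambda: float
    loglik: float
    levels: np.ndarray
    k_chosen: np.ndarray
    n_trials: np.ndarray
    jnd: float = float("nan")
    se_jnd: float = float("nan")
    jnd_ci: tuple[float, float] = (float("nan"), float("nan"))
    weber: float = float("nan")
    deviance: float = float("nan")
    gof_p: float = float("nan")
    uninformative: bool = False
    flags: list = field(default_factory=list)
    # sign of the map from native stimulus units to the fitted axis (the TTA
    # task is fitted against -TTA so that psi increases with "earliness")
    x_sign: float = 1.0

    @property
    def pse_native(self) -> float:
        """PSE in native stimulus units (TTA in s, speed in km/h)."""
        return self.x_sign * self.pse

    def predict(self, x) -> np.ndarray:
        return _psi(np.asarray(x, dtype=float), self.pse, self.slope_sigma,
                    self.guess_gamma, self.lapse_lambda)


def _psi(x, pse, sigma, gamma, lam):
    return gamma + (1.0 - gamma - lam) * stats.norm.cdf((x - pse) / sigma)


def _nll(params, x, k, n):
    pse, sigma, gamma, lam = params
    p = np.clip(_psi(x, pse, sigma, gamma, lam), 1e-12, 1 - 1e-12)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def fit_psychometric(levels, k_chosen, n_trials,
                     gamma_bounds=(0.0, 0.05), lambda_bounds=(0.0, 0.1),
                     n_starts: int = 5, start=None) -> PsychFit:
    """Maximum-likelihood cumulative-normal fit with multistart.

    ``levels`` are the stimulus values, ``k_chosen`` the number of
    "faster"/"earlier" choices, ``n_trials`` the trials per level.  The
    bounded guess/lapse rates create local optima, hence an
    ``n_starts x n_starts`` grid of (pse, sigma) starting points.
    """
    x = np.asarray(levels, dtype=float)
    k = np.asarray(k_chosen, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct stimulus levels")
    if np.any(n < 1):
        raise ValueError("every level needs at least one trial")
    rng_span = float(x.max() - x.min())
    bounds = [(x.min(), x.max()),
              (rng_span * 1e-3, rng_span * 10),
              gamma_bounds, lambda_bounds]
    best = None
    if start is not None:
        # warm start (bootstrap refits): one optimization from known params
        x0 = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        starts = [x0]
    else:
        pse_grid = np.linspace(x.min(), x.max(), n_starts)
        sig_grid = np.geomspace(rng_span / 20, rng_span, n_starts)
        starts = [[p0, s0, 0.01, 0.02] for p0 in pse_grid for s0 in sig_grid]
    for x0 in starts:
        res = optimize.minimize(_nll, x0=x0, args=(x, k, n),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    pse, sigma, gamma, lam = best.x
    ll = -best.fun
    fit = PsychFit(pse=float(pse), slope_sigma=float(sigma),
                   guess_gamma=float(gamma), lapse_lambda=float(lam),
                   loglik=ll, levels=x, k_chosen=k, n_trials=n)
    # uninformative: the fit explains essentially nothing beyond a constant
    p_const = np.clip(k.sum() / n.sum(), 1e-12, 1 - 1e-12)
    ll_const = float(np.sum(k * np.log(p_const) + (n - k) * np.log(1 - p_const)))
    if ll - ll_const < 1e-6 or sigma >= bounds[1][1] * 0.999:
        fit.uninformative = True
        fit.flags.append("uninformative")
    try:
        fit.jnd = jnd(fit)
    except ValueError:
        fit.flags.append("jnd-undefined")
    if fit.uninformative:
        fit.flags.append("jnd-unreliable")
    return fit


def jnd(fit: PsychFit) -> float:
    """Half the distance between the 75% and 25% points of psi.

    Quantiles are taken on the full function including the guess and lapse
    asymptotes; raises when 0.25 or 0.75 lies outside their reachable range.
    """
    gamma, lam = fit.guess_gamma, fit.lapse_lambda
    lo, hi = gamma, 1.0 - lam
    if not (lo < 0.25 < hi and lo < 0.75 < hi):
        raise ValueError("0.25/0.75 response levels outside the asymptote range")
    scale = 1.0 - gamma - lam
    x25 = fit.pse + fit.slope_sigma * stats.norm.ppf((0.25 - gamma) / scale)
    x75 = fit.pse + fit.slope_sigma * stats.norm.ppf((0.75 - gamma) / scale)
    return float((x75 - x25) / 2.0)


def weber(jnd_value: float, standard: float) -> float:
    """Weber fraction: JND divided by the standard stimulus magnitude."""
    if standard <= 0:
        raise ValueError("standard must be positive")
    return float(jnd_value / standard)


def deviance_gof(fit: PsychFit, n_boot: int = 1000, seed: int = 0):
    """Deviance vs the saturated model with a parametric-bootstrap p.

    Dev = 2 (l_saturated - l_fit); p is the fraction of bootstrap deviances
    (data resimulated from the fitted psi, refit) at or above the observed.
    """
    x, k, n = fit.levels, fit.k_chosen, fit.n_trials
    p_hat = np.clip(k / n, 1e-12, 1 - 1e-12)
    ll_sat = float(np.sum(k * np.log(p_hat) + (n - k) * np.log(1 - p_hat)))
    dev = 2.0 * (ll_sat - fit.loglik)
    rng = np.random.default_rng(seed)
    p_fit = fit.predict(x)
    count = 0
    for _ in range(n_boot):
        k_b = rng.binomial(n.astype(int), p_fit)
        f_b = fit_psychometric(x, k_b, n, start=[fit.pse, fit.slope_sigma,
                                                 fit.guess_gamma,
                                                 fit.lapse_lambda])
        p_b = np.clip(k_b / n, 1e-12, 1 - 1e-12)
        ll_sat_b = float(np.sum(k_b * np.log(p_b) + (n - k_b) * np.log(1 - p_b)))
        if 2.0 * (ll_sat_b - f_b.loglik) >= dev - 1e-12:
            count += 1
    fit.deviance = float(dev)
    fit.gof_p = count / n_boot
    return fit.deviance, fit.gof_p


def bootstrap_jnd(fit: PsychFit, n_boot: int = 500, seed: int = 0):
    """Parametric-bootstrap SE and 95% CI for the JND."""
    rng = np.random.default_rng(seed)
    x, n = fit.levels, fit.n_trials
    p_fit = fit.predict(x)
    jnds = []
    for _ in range(n_boot):
        k_b = rng.binomial(n.astype(int), p_fit)
        f_b = fit_psychometric(x, k_b, n, start=[fit.pse, fit.slope_sigma,
                                                 fit.guess_gamma,
                                                 fit.lapse_lambda])
        if np.isfinite(f_b.jnd):
            jnds.append(f_b.jnd)
    jnds = np.asarray(jnds)
    fit.se_jnd = float(np.std(jnds, ddof=1))
    fit.jnd_ci = (float(np.percentile(jnds, 2.5)),
                  float(np.percentile(jnds, 97.5)))
    return fit.se_jnd, fit.jnd_ci


def _aggregate(values: np.ndarray, chosen: np.ndarray):
    levels = np.unique(values)
    k = np.array([chosen[values == lv].sum() for lv in levels], dtype=float)
    n = np.array([(values == lv).sum() for lv in levels], dtype=float)
    return levels, k, n


def fit_from_trials(trials, task: str, standard: float) -> PsychFit:
    """Fit one participant-task psychometric function from the trial table.

    For the speed task the response is "comparison judged faster" against
    comparison speed; for the TTA task "comparison judged earlier" is
    recoded so that the fitted function increases with earliness, then the
    JND is expressed in seconds of TTA.
    """
    df = trials[trials["task"] == task]
    if task == "speed":
        xvals = df["comparison_speed"].to_numpy(dtype=float)
        chosen = df["chose_comparison"].to_numpy(dtype=bool)
    else:
        # proportion "earlier" rises as comparison TTA falls; fit against
        # -TTA so the function is increasing, then map PSE back
        xvals = -df["comparison_tta"].to_numpy(dtype=float)
        chosen = df["chose_comparison"].to_numpy(dtype=bool)
    levels, k, n = _aggregate(xvals, chosen)
    fit = fit_psychometric(levels, k, n)
    if task == "tta":
        fit.x_sign = -1.0
    fit.weber = weber(fit.jnd, standard) if np.isfinite(fit.jnd) else float("nan")
    return fit


def interval_bias_fit(trials, task: str, grid) -> PsychFit:
    """Interval-bias fit: P(chose interval 2) against interval-2 stimulus.

    A PSE below (speed) / above (TTA) the standard indicates a propensity to
    report the second interval as faster / arriving earlier.
    """
    df = trials[trials["task"] == task]
    chose2 = (df["chose_comparison"] == df["standard_first"]).to_numpy(dtype=bool)
    if task == "speed":
        x2 = np.where(df["standard_first"], df["comparison_speed"],
                      grid.standard_speed).astype(float)
        standard = grid.standard_speed
        xfit = x2
    else:
        x2 = np.where(df["standard_first"], df["comparison_tta"],
                      grid.standard_tta).astype(float)
        standard = grid.standard_tta
        xfit = -x2  # increasing in earliness
    levels, k, n = _aggregate(xfit, chose2)
    fit = fit_psychometric(levels, k, n)
    if task == "tta":
        fit.x_sign = -1.0
    fit.flags.append(f"interval_bias:{standard - fit.pse_native:+.3f}")
    return fit
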