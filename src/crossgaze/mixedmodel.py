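"""Hierarchical logistic regression of trial correctness on gaze metrics.

Model: logit P(correct) = X beta + Z u with crossed random factors
(observer, comparison speed level, comparison TTA level), random intercepts
and uncorrelated random slopes (diagonal covariance), estimated by
Laplace-approximate maximum likelihood.  The engine follows the standard
GLMM formulation: with the spherical parametrization u = Lambda v,
v ~ N(0, I), the Laplace log-likelihood at the joint conditional mode
(beta, v-hat) is

    l = loglik(y | eta-hat) - ||v-hat||^2 / 2
        - log det(I + Lambda Z'WZ Lambda) / 2,

maximized over the variance parameters with the fixed effects profiled into
the inner penalized Newton iteration.  Fixed-effect predictors are z-scored
before fitting and reported on that scale.

When a model does not converge the simplification ladder drops random
slopes and finally retains intercepts only, recording log-likelihoods and
AICs of every attempt; if nothing converges a plain logistic fit is
returned with a prominent flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MixedModelSpec",
    "MixedModelReport",
    "fit_mixed_logistic",
    "simplify_ladder",
    "vif",
    "DEFAULT_FIXED_EFFECTS",
]

DEFAULT_FIXED_EFFECTS = ["gain", "n_saccades", "mean_amplitude",
                         "rel_dev_h", "rel_dev_v", "abs_dev_h", "abs_dev_v"]


@dataclass(frozen=True)
class MixedModelSpec:
    fixed: tuple[str, ...] = tuple(DEFAULT_FIXED_EFFECTS)
    random_factors: tuple[str, ...] = ("participant_id", "comparison_speed",
                                       "comparison_tta")
    # random slopes per factor: () for intercept-only, or fixed-effect names
    random_slopes: dict = field(default_factory=dict)
    response: str = "correct"

    def slopes_for(self, factor: str) -> tuple[str, ...]:
        return tuple(self.random_slopes.get(factor, ()))


@dataclass
class MixedModelReport:
    estimates: pd.DataFrame  # term, estimate, se, z, p
    random_variances: dict  # (factor, term) -> variance
    loglik: float
    aic: float
    vif: dict
    converged: bool
    ladder_record: list = field(default_factory=list)
    scaling: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def vif(fixed_design: pd.DataFrame) -> dict:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j)."""
    X = fixed_design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        corr = np.corrcoef(X, rowvar=False)
        aliased = [fixed_design.columns[j] for i, j in zip(*np.where(
            np.abs(corr) > 1 - 1e-10)) if i < j]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    out = {}
    for j, col in enumerate(fixed_design.columns):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        tss = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        out[col] = float(1.0 / (1.0 - min(r2, 1 - 1e-12)))
    return out


def _build_random_design(data: pd.DataFrame, X_std: pd.DataFrame,
                         spec: MixedModelSpec):
    """Z matrix plus a map from columns to (factor, term) variance groups."""
    Z_cols, groups = [], []
    for factor in spec.random_factors:
        levels = pd.unique(data[factor])
        if len(levels) < 2:
            raise ValueError(f"random factor {factor} needs >= 2 levels")
        idx = pd.Categorical(data[factor], categories=levels).codes
        terms = ("__intercept__",) + spec.slopes_for(factor)
        for term in terms:
            x = np.ones(len(data)) if term == "__intercept__" \
                else X_std[term].to_numpy(dtype=float)
            for li in range(len(levels)):
                Z_cols.append(np.where(idx == li, x, 0.0))
                groups.append((factor, term))
    Z = np.column_stack(Z_cols)
    group_keys = sorted(set(groups), key=groups.index)
    group_index = np.array([group_keys.index(g) for g in groups])
    return Z, group_keys, group_index


def _inner_mode_u(y, Xbeta, ZL, v0, max_iter=60, tol=1e-11):
    """Penalized Newton over the spherical random effects v (beta fixed)."""
    q = ZL.shape[1]
    v = v0.copy()
    f_old = -np.inf
    for _ in range(max_iter):
        eta = Xbeta + ZL @ v
        mu = 1.0 / (1.0 + np.exp(-eta))
        f = float(np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * v @ v)
        w = mu * (1.0 - mu) + 1e-10
        grad = ZL.T @ (y - mu) - v
        if abs(f - f_old) < tol and np.max(np.abs(grad)) < 1e-8:
            break
        f_old = f
        H = ZL.T @ (ZL * w[:, None]) + np.eye(q)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        for _h in range(25):
            v_n = v + step
            eta_n = Xbeta + ZL @ v_n
            f_n = float(np.sum(y * eta_n - np.logaddexp(0.0, eta_n))
                        - 0.5 * v_n @ v_n)
            if f_n >= f - 1e-12:
                break
            step = step / 2.0
        v = v_n
    eta = Xbeta + ZL @ v
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu) + 1e-10
    return v, w, float(np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * v @ v)


def _laplace_loglik(params, y, X, Z, group_index, n_theta, state):
    """Laplace objective over (theta, beta); u is profiled out inside."""
    theta, beta = params[:n_theta], params[n_theta:]
    sigma = np.exp(theta)[group_index]
    ZL = Z * sigma[None, :]
    v, w, f = _inner_mode_u(y, X @ beta, ZL, state["v"])
    state["v"] = v
    M = ZL.T @ (ZL * w[:, None]) + np.eye(Z.shape[1])
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return -1e10
    return f - 0.5 * logdet


def fit_mixed_logistic(data: pd.DataFrame, spec: MixedModelSpec | None = None,
                       max_outer_iter: int = 200) -> MixedModelReport:
    """Fit the logistic mixed model by Laplace-approximate ML.

    Raises ``ConvergenceWarning``-style ``RuntimeError`` on non-convergence
    so that :func:`simplify_ladder` can advance; use the ladder for the
    paper-style workflow.
    """
    spec = spec or MixedModelSpec()
    df = data.dropna(subset=list(spec.fixed) + [spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(dtype=float)
    X_raw = df[list(spec.fixed)]
    scaling = {c: (float(X_raw[c].mean()), float(X_raw[c].std(ddof=0)))
               for c in X_raw.columns}
    X_std = (X_raw - X_raw.mean()) / X_raw.std(ddof=0)
    X = np.column_stack([np.ones(len(df)), X_std.to_numpy(dtype=float)])
    terms = ["(Intercept)"] + list(spec.fixed)

    Z, group_keys, group_index = _build_random_design(df, X_std, spec)
    n_theta = len(group_keys)
    state = {"v": np.zeros(Z.shape[1])}

    def neg(params):
        return -_laplace_loglik(params, y, X, Z, group_index, n_theta, state)

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta0 = sm.Logit(y, X).fit(disp=0, maxiter=100).params
        x0 = np.concatenate([np.full(n_theta, np.log(0.5)), beta0])
        bounds = [(-8.0, 3.0)] * n_theta + [(None, None)] * X.shape[1]
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": max_outer_iter,
                                         "ftol": 1e-12, "gtol": 1e-6})
    converged = bool(res.success)
    theta, beta = res.x[:n_theta], res.x[n_theta:]
    ll = -float(res.fun)
    if not converged:
        raise RuntimeError(f"mixed model did not converge: {res.message}")

    sigma = np.exp(theta)[group_index]
    ZL_fin = Z * sigma[None, :]
    v, w, _f = _inner_mode_u(y, X @ beta, ZL_fin, state["v"])
    # conditional covariance of beta from the joint (beta, v) Hessian
    p, q = X.shape[1], Z.shape[1]
    ZL = Z * sigma[None, :]
    Xw = X * w[:, None]
    H = np.zeros((p + q, p + q))
    H[:p, :p] = X.T @ Xw
    H[:p, p:] = X.T @ (ZL * w[:, None])
    H[p:, :p] = H[:p, p:].T
    H[p:, p:] = ZL.T @ (ZL * w[:, None]) + np.eye(q)
    cov = np.linalg.inv(H)[:p, :p]
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    est = pd.DataFrame({"term": terms, "estimate": beta, "se": se,
                        "z": z, "p": pvals})
    rv = {g: float(np.exp(2 * th)) for g, th in zip(group_keys, theta)}
    aic = -2.0 * ll + 2.0 * (p + n_theta)
    vifs = vif(X_std)
    return MixedModelReport(estimates=est, random_variances=rv, loglik=ll,
                            aic=aic, vif=vifs, converged=True,
                            scaling=scaling)


def _ladder_specs(spec: MixedModelSpec) -> list[tuple[str, MixedModelSpec]]:
    from dataclasses import replace

    steps = [("full-uncorrelated", spec)]
    if any(spec.slopes_for(f) for f in spec.random_factors
           if f != "participant_id"):
        steps.append(("observer-slopes-only", replace(spec, random_slopes={
            f: spec.slopes_for(f) if f == "participant_id" else ()
            for f in spec.random_factors})))
    if any(spec.slopes_for(f) for f in spec.random_factors):
        steps.append(("intercepts-only", replace(spec, random_slopes={})))
    return steps


def simplify_ladder(data: pd.DataFrame,
                    spec: MixedModelSpec | None = None) -> MixedModelReport:
    """Fit with progressive random-effects simplification.

    Tries (1) the full uncorrelated model, (2) random slopes for the
    observer only, (3) random intercepts only, stopping at the first
    converged fit; every attempt's log-likelihood/AIC is recorded for the
    parsimony comparison.  If nothing converges a plain logistic fit is
    returned with a prominent flag.
    """
    spec = spec or MixedModelSpec()
    record = []
    result = None
    for name, s in _ladder_specs(spec):
        try:
            rep = fit_mixed_logistic(data, s)
            record.append({"step": name, "converged": True,
                           "loglik": rep.loglik, "aic": rep.aic})
            if result is None:
                result = rep
                result.flags.append(f"converged-at:{name}")
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            record.append({"step": name, "converged": False,
                           "error": str(exc)})
    if result is None:
        import statsmodels.api as sm

        df = data.dropna(subset=list(spec.fixed) + [spec.response])
        X_std = (df[list(spec.fixed)] - df[list(spec.fixed)].mean()) \
            / df[list(spec.fixed)].std(ddof=0)
        design = np.column_stack([np.ones(len(df)), X_std.to_numpy()])
        res = sm.Logit(df[spec.response].to_numpy(dtype=float), design).fit(disp=0)
        est = pd.DataFrame({
            "term": ["(Intercept)"] + list(spec.fixed),
            "estimate": res.params, "se": res.bse, "z": res.tvalues,
            "p": res.pvalues})
        result = MixedModelReport(
            estimates=est, random_variances={}, loglik=float(res.llf),
            aic=float(res.aic), vif=vif(X_std), converged=False,
            flags=["FALLBACK: plain logistic fit; no mixed model converged"])
    result.ladder_record = record
    return result
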