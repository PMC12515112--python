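"""Weighted Gaussian linear mixed models by REML.

The meta-models of step 3 are Gaussian LMMs with crossed random
intercepts and *known inverse-variance weights*: row ``k`` has residual
variance ``sigma^2 / w_k`` with ``w_k = 1 / SE_k^2`` supplied by the
data and ``sigma^2`` estimated. General-purpose Python mixed-model
fitters do not expose this weighting convention, so the REML machinery
is implemented here for the specific structure needed:

    y = X beta + sum_j Z_j b_j + eps,
    b_j ~ N(0, sigma_j^2 I),  eps ~ N(0, sigma^2 W^{-1})

with ``W = diag(w)``. The variance ratios ``gamma_j = sigma_j^2 /
sigma^2`` are profiled out of the REML criterion and optimized by
quasi-Newton on the log scale; ``sigma^2`` and ``beta`` then have
closed forms. Degrees of freedom for fixed-effect t-tests use the
Satterthwaite approximation, with the asymptotic covariance of the
variance components taken from the numerically differentiated REML
information matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import t as t_dist

from cesdemog.errors import ConvergenceError

logger = logging.getLogger(__name__)

_LOG_GAMMA_FLOOR = -30.0  # exp(-30) ~ 1e-13: effectively a zero variance ratio


@dataclass
class WeightedLMMResult:
    """REML fit of a weighted LMM with crossed random intercepts."""

    beta: np.ndarray
    cov_beta: np.ndarray
    fixed_names: list[str]
    sigma2: float  # residual variance (for unit weight)
    varcomps: dict[str, float]  # random-intercept variances by factor name
    df: np.ndarray  # Satterthwaite df per fixed effect
    loglik: float  # REML log-likelihood
    converged: bool
    n: int
    boundary: list[str] = field(default_factory=list)  # factors with ~0 variance

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def tvalues(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * t_dist.sf(np.abs(self.tvalues), self.df)


def _v0_cholesky(winv: np.ndarray, Zs: list[np.ndarray], gamma: np.ndarray):
    V0 = np.diag(winv)
    for g, Z in zip(gamma, Zs):
        if g > 0:
            V0 += g * (Z @ Z.T)
    return cho_factor(V0, lower=True)


def _profiled_quantities(
    y: np.ndarray, X: np.ndarray, winv: np.ndarray, Zs: list[np.ndarray], gamma: np.ndarray
):
    """GLS beta, profiled sigma^2 and the REML log-likelihood at gamma."""
    n, p = X.shape
    c, low = _v0_cholesky(winv, Zs, gamma)
    logdet_v0 = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    XtViy = X.T @ Vi_y
    beta = np.linalg.solve(XtViX, XtViy)
    r = y - X @ beta
    rss = float(r @ cho_solve((c, low), r))
    sigma2 = rss / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    loglik = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_v0 + logdet_xvx
    )
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    return beta, cov_beta, sigma2, loglik


def _neg_reml_theta(
    theta: np.ndarray, y: np.ndarray, X: np.ndarray, winv: np.ndarray, Zs: list[np.ndarray]
) -> float:
    """-REML loglik as a function of the variance components themselves,
    theta = (sigma^2, sigma_1^2, ..., sigma_J^2). Used for the
    Satterthwaite information matrix."""
    n, p = X.shape
    sigma2 = theta[0]
    if sigma2 <= 0:
        return np.inf
    V = sigma2 * np.diag(winv)
    for s2, Z in zip(theta[1:], Zs):
        V += s2 * (Z @ Z.T)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ cho_solve((c, low), y))
    r = y - X @ beta
    quad = float(r @ cho_solve((c, low), r))
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    return 0.5 * (logdet_v + logdet_xvx + quad + (n - p) * np.log(2.0 * np.pi))


def _cov_beta_at_theta(
    theta: np.ndarray, X: np.ndarray, winv: np.ndarray, Zs: list[np.ndarray]
) -> np.ndarray:
    V = theta[0] * np.diag(winv)
    for s2, Z in zip(theta[1:], Zs):
        V += s2 * (Z @ Z.T)
    c, low = cho_factor(V, lower=True)
    return np.linalg.inv(X.T @ cho_solve((c, low), X))


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _satterthwaite_df(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    winv: np.ndarray,
    Zs: list[np.ndarray],
) -> np.ndarray:
    """Satterthwaite df for each fixed-effect coefficient.

    df_i = 2 f_i^2 / Var(f_i), where f_i(theta) = [ (X'V(theta)^-1 X)^-1 ]_ii
    and Var(f_i) = g_i' A g_i with A the inverse REML information.
    Falls back to the residual df where the information matrix is not
    usable (e.g., a variance component on the boundary).
    """
    n, p = X.shape
    resid_df = float(n - p)
    try:
        H = _numeric_hessian(lambda th: _neg_reml_theta(th, y, X, winv, Zs), theta)
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(p, resid_df)
    if not np.all(np.isfinite(A)):
        return np.full(p, resid_df)

    q = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1e-8)
    # gradient of the full cov matrix diag wrt each variance component
    grads = np.empty((q, p))
    try:
        for k in range(q):
            e = np.zeros(q); e[k] = h[k]
            up = np.diag(_cov_beta_at_theta(np.maximum(theta + e, 0.0), X, winv, Zs))
            lo_theta = theta - e
            if lo_theta[0] <= 0:
                lo_theta = theta
                dn = np.diag(_cov_beta_at_theta(theta, X, winv, Zs))
                grads[k] = (up - dn) / h[k]
                continue
            dn = np.diag(_cov_beta_at_theta(np.maximum(lo_theta, 0.0), X, winv, Zs))
            grads[k] = (up - dn) / (2 * h[k])
    except np.linalg.LinAlgError:
        return np.full(p, resid_df)

    f = np.diag(_cov_beta_at_theta(theta, X, winv, Zs))
    df = np.empty(p)
    for i in range(p):
        g = grads[:, i]
        var_f = float(g @ A @ g)
        if var_f <= 0 or not np.isfinite(var_f):
            df[i] = resid_df
        else:
            df[i] = 2.0 * f[i] ** 2 / var_f
    return np.clip(df, 1.0, None)


def fit_weighted_lmm_core(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    random_factors: dict[str, np.ndarray],
    fixed_names: list[str] | None = None,
    force_zero_random_effects: bool = False,
) -> WeightedLMMResult:
    """Fit the weighted LMM by profiled REML.

    Parameters
    ----------
    y, X, weights
        Response, fixed design and per-row inverse-variance weights.
    random_factors
        Mapping factor name -> integer codes (0..q-1) per row; each
        factor contributes an independent random intercept per level.
    force_zero_random_effects
        Skip variance-ratio optimization and fit at all ratios 0,
        which reduces the model to weighted least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    n, p = X.shape
    if fixed_names is None:
        fixed_names = [f"x{i}" for i in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is rank deficient")
    winv = 1.0 / weights
    names = list(random_factors)
    Zs = []
    for name in names:
        codes = np.asarray(random_factors[name])
        levels = np.unique(codes)
        if len(levels) < 2:
            raise ValueError(f"random factor {name!r} needs >= 2 levels")
        Z = (codes[:, None] == levels[None, :]).astype(float)
        Zs.append(Z)
    J = len(Zs)

    if force_zero_random_effects or J == 0:
        gamma_hat = np.zeros(J)
        beta, cov_beta, sigma2, loglik = _profiled_quantities(y, X, winv, Zs, gamma_hat)
        return WeightedLMMResult(
            beta=beta, cov_beta=cov_beta, fixed_names=fixed_names, sigma2=sigma2,
            varcomps={name: 0.0 for name in names},
            df=np.full(p, float(n - p)), loglik=loglik, converged=True, n=n,
            boundary=list(names),
        )

    def objective(zeta: np.ndarray) -> float:
        gamma = np.exp(zeta)
        try:
            _, _, _, ll = _profiled_quantities(y, X, winv, Zs, gamma)
        except np.linalg.LinAlgError:
            return np.inf
        return -ll

    # scale-aware starts: gamma is a variance ratio, and the residual
    # variance for unit weight is roughly var(y * sqrt(w))
    base = float(np.var(y * np.sqrt(weights))) or 1.0
    ratio0 = np.log(np.var(y) / base) if np.var(y) > 0 else 0.0
    starts = [np.full(J, v) for v in (ratio0, ratio0 - 4.0, ratio0 + 4.0, 0.0)]
    best = None
    for z0 in starts:
        res = minimize(
            objective,
            np.clip(z0, _LOG_GAMMA_FLOOR, 20.0),
            method="L-BFGS-B",
            bounds=[(_LOG_GAMMA_FLOOR, 20.0)] * J,
            options={"maxiter": 500, "ftol": 1e-13},
        )
        if best is None or (res.success and res.fun < best.fun - 1e-10) or (
            not best.success and res.success
        ):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("weighted LMM REML optimization failed")
    converged = bool(best.success)
    gamma_hat = np.exp(best.x)
    boundary = [name for name, z in zip(names, best.x) if z <= _LOG_GAMMA_FLOOR + 1e-6]
    gamma_hat[np.array([z <= _LOG_GAMMA_FLOOR + 1e-6 for z in best.x])] = 0.0
    if boundary:
        logger.warning("singular fit: variance of %s estimated at 0", boundary)

    beta, cov_beta, sigma2, loglik = _profiled_quantities(y, X, winv, Zs, gamma_hat)
    theta = np.concatenate([[sigma2], gamma_hat * sigma2])
    df = _satterthwaite_df(theta, y, X, winv, Zs)
    return WeightedLMMResult(
        beta=beta,
        cov_beta=cov_beta,
        fixed_names=fixed_names,
        sigma2=sigma2,
        varcomps={name: float(g * sigma2) for name, g in zip(names, gamma_hat)},
        df=df,
        loglik=loglik,
        converged=converged,
        n=n,
        boundary=boundary,
    )
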