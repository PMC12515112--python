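"""Cormack-Jolly-Seber survival model with a transience mixture.

Annual apparent adult survival is estimated per species-scheme from
capture histories of adults, conditional on first capture. The model
has three parameter blocks:

* ``phi_t`` — survival over interval ``t -> t + 1``, shared by all
  sites within the scheme (``T - 1`` parameters);
* ``tau`` — the probability that a newly captured adult is a resident;
  a transient (probability ``1 - tau``) leaves immediately and is never
  recaptured;
* ``p_s`` — recapture probability, constant over years but specific to
  the site of first capture.

For an individual first caught at occasion ``f`` at site ``s`` with
detection history ``omega``, the likelihood is the mixture

    L = (1 - tau) * [omega has no detection after f] + tau * L_CJS

where ``L_CJS`` runs the usual CJS product up to the last detection
``l`` and closes with the chi recursion ``chi_T = 1``,
``chi_t = (1 - phi_t) + phi_t (1 - p_s) chi_{t+1}`` (the probability of
never being seen after occasion ``t``).

Fitting is by maximum likelihood on the logit scale with random
restarts; standard errors come from the inverse observed information,
mapped to the probability scale by the delta method. Two robustness
filters mirror common practice with constant-effort data: sites with
recapture estimates outside (0.10, 0.90) are excluded, and annual
survival estimates with SE outside (0.01, 0.25) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from cesdemog.data import CaptureHistorySet
from cesdemog.errors import ConvergenceError, DataError

logger = logging.getLogger(__name__)

_PFLOOR = 1e-12


@dataclass
class CJSParameters:
    """Natural-scale parameters of the transient-CJS model."""

    phi: np.ndarray  # (T - 1,) interval survival
    tau: float  # residency probability
    p: np.ndarray  # (S,) site recapture

    def to_unconstrained(self) -> np.ndarray:
        return np.concatenate([logit(self.phi), [logit(self.tau)], logit(self.p)])

    @staticmethod
    def from_unconstrained(theta: np.ndarray, n_intervals: int, n_sites: int) -> "CJSParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (n_intervals + 1 + n_sites,):
            raise ValueError(
                f"expected {n_intervals + 1 + n_sites} parameters, got {theta.shape}"
            )
        return CJSParameters(
            phi=expit(theta[:n_intervals]),
            tau=float(expit(theta[n_intervals])),
            p=expit(theta[n_intervals + 1 :]),
        )


@dataclass
class CJSFit:
    """Maximum-likelihood fit of the transient-CJS model."""

    species: str
    scheme: str
    years: np.ndarray
    site_codes: list[str]
    phi_hat: np.ndarray
    phi_se: np.ndarray
    tau_hat: float
    tau_se: float
    p_hat: np.ndarray
    p_se: np.ndarray
    loglik: float
    converged: bool
    se_available: bool
    vcov_unconstrained: np.ndarray | None
    n_individuals: int
    n_dropped_final_year: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class _SufficientStats:
    """Aggregated histories: identical (site, first, last, n detections)
    rows collapse to one weighted entry."""

    site: np.ndarray
    first: np.ndarray
    last: np.ndarray
    ndet: np.ndarray
    count: np.ndarray
    n_occasions: int
    n_sites: int


def _sufficient_stats(histories: CaptureHistorySet, drop_final_first: bool = False) -> _SufficientStats:
    det = histories.detections
    if det.shape[0] == 0:
        raise DataError("empty capture history set")
    T = histories.n_occasions
    first = histories.first
    last = det.shape[1] - 1 - np.argmax(det[:, ::-1], axis=1)
    ndet = det.sum(axis=1)
    site = histories.site_index
    keep = np.ones(len(first), dtype=bool)
    if drop_final_first:
        keep = first < T - 1
    key = (site[keep] * T + first[keep]) * T * (T + 1) + last[keep] * (T + 1) + ndet[keep]
    uniq, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
    # decode
    ndet_u = uniq % (T + 1)
    rest = uniq // (T + 1)
    last_u = rest % T
    rest = rest // T
    first_u = rest % T
    site_u = rest // T
    return _SufficientStats(
        site=site_u.astype(np.int64),
        first=first_u.astype(np.int64),
        last=last_u.astype(np.int64),
        ndet=ndet_u.astype(np.int64),
        count=counts.astype(np.float64),
        n_occasions=T,
        n_sites=histories.n_sites,
    )


def _nll_from_stats(stats: _SufficientStats, theta: np.ndarray) -> float:
    T = stats.n_occasions
    S = stats.n_sites
    params = CJSParameters.from_unconstrained(theta, T - 1, S)
    return _nll_natural(stats, params.phi, params.tau, params.p)


def _nll_natural(
    stats: _SufficientStats, phi_in: np.ndarray, tau_in: float, p_in: np.ndarray
) -> float:
    T = stats.n_occasions
    S = stats.n_sites
    phi = np.clip(np.asarray(phi_in, dtype=float), _PFLOOR, 1 - _PFLOOR)
    tau = min(max(float(tau_in), _PFLOOR), 1.0)
    p = np.clip(np.asarray(p_in, dtype=float), _PFLOOR, 1 - _PFLOOR)

    # chi[s, t]: probability of never being detected after occasion t
    chi = np.ones((S, T))
    for t in range(T - 2, -1, -1):
        chi[:, t] = (1 - phi[t]) + phi[t] * (1 - p) * chi[:, t + 1]

    clogphi = np.concatenate([[0.0], np.cumsum(np.log(phi))])  # clogphi[t] = sum_{u<t} log phi_u
    s, f, l, k = stats.site, stats.first, stats.last, stats.ndet
    log_cjs = (
        clogphi[l]
        - clogphi[f]
        + (k - 1) * np.log(p[s])
        + ((l - f) - (k - 1)) * np.log(1 - p[s])
        + np.log(chi[s, l])
    )
    lik = tau * np.exp(log_cjs)
    never_again = l == f
    lik = np.where(never_again, lik + (1 - tau), lik)
    lik = np.maximum(lik, 1e-300)
    return float(-np.sum(stats.count * np.log(lik)))


def neg_log_likelihood(histories: CaptureHistorySet, params: CJSParameters) -> float:
    """Negative log-likelihood of the transient-CJS model.

    Conditional on each individual's first capture; individuals first
    caught in the final year contribute likelihood 1 and hence 0.
    Accepts boundary values (``phi = 0``, ``tau = 1``) on the natural
    scale.
    """
    phi = np.asarray(params.phi, dtype=float)
    p = np.asarray(params.p, dtype=float)
    if not (
        np.all(np.isfinite(phi))
        and np.all(np.isfinite(p))
        and np.isfinite(params.tau)
    ):
        raise ValueError("parameters must be finite")
    if np.any(phi < 0) or np.any(phi > 1) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 < params.tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    stats = _sufficient_stats(histories)
    return _nll_natural(stats, phi, params.tau, p)


def _numeric_hessian(fun, theta: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(theta)
    h = step * np.maximum(1.0, np.abs(theta))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            f_pp = fun(theta + ei + ej)
            f_pm = fun(theta + ei - ej)
            f_mp = fun(theta - ei + ej)
            f_mm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    return H


def fit_cjs_transient(
    histories: CaptureHistorySet,
    n_starts: int = 5,
    seed: int | None = None,
    gtol: float = 1e-6,
    maxiter: int = 1000,
) -> CJSFit:
    """Fit the transient-CJS model by maximum likelihood.

    ``n_starts`` quasi-Newton runs are launched: one from a neutral
    heuristic point and the rest from random logit-scale perturbations,
    seeded for reproducibility. The best converged run is returned.

    Raises
    ------
    DataError
        If fewer than three occasions remain or the data contain no
        recapture at all (the survival parameters then sit on the
        likelihood boundary).
    ConvergenceError
        If no start converges.
    """
    T = histories.n_occasions
    if T < 3:
        raise DataError(f"need >= 3 occasions, got {T}")
    n_dropped = int(np.sum(histories.first == T - 1))
    if n_dropped:
        logger.info(
            "%s/%s: dropped %d individuals first caught in the final year (no information)",
            histories.scheme,
            histories.species,
            n_dropped,
        )
    stats = _sufficient_stats(histories, drop_final_first=True)
    if not np.any(stats.last > stats.first):
        raise DataError("no recaptures in the data; survival is not estimable")
    S = histories.n_sites
    n_par = (T - 1) + 1 + S
    rng = np.random.default_rng(seed)

    def nll(theta: np.ndarray) -> float:
        return _nll_from_stats(stats, theta)

    start0 = np.concatenate(
        [np.full(T - 1, logit(0.5)), [logit(0.7)], np.full(S, logit(0.3))]
    )
    best = None
    messages: list[str] = []
    for k in range(n_starts):
        theta0 = start0 if k == 0 else start0 + rng.normal(0.0, 1.0, n_par)
        res = minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        messages.append(f"start {k}: success={res.success} nll={res.fun:.6f}")
        if res.success and (best is None or res.fun < best.fun - 1e-9):
            best = res
    if best is None:
        raise ConvergenceError(
            f"{histories.scheme}/{histories.species}: no start converged "
            f"({'; '.join(messages)})"
        )

    theta = best.x
    params = CJSParameters.from_unconstrained(theta, T - 1, S)
    se_available = True
    vcov = None
    se_theta = np.full(n_par, np.nan)
    try:
        H = _numeric_hessian(nll, theta)
        vcov = np.linalg.inv(H)
        diag = np.diag(vcov)
        if np.any(diag < 0) or not np.all(np.isfinite(diag)):
            raise np.linalg.LinAlgError("negative or non-finite variance")
        se_theta = np.sqrt(diag)
    except np.linalg.LinAlgError as exc:
        se_available = False
        messages.append(f"information matrix not invertible: {exc}")
        logger.warning(
            "%s/%s: SEs unavailable (%s)", histories.scheme, histories.species, exc
        )

    # delta method: d expit / d theta = pi (1 - pi)
    phi_se = se_theta[: T - 1] * params.phi * (1 - params.phi)
    tau_se = float(se_theta[T - 1] * params.tau * (1 - params.tau))
    p_se = se_theta[T:] * params.p * (1 - params.p)

    return CJSFit(
        species=histories.species,
        scheme=histories.scheme,
        years=histories.years,
        site_codes=list(histories.site_codes),
        phi_hat=params.phi,
        phi_se=phi_se,
        tau_hat=params.tau,
        tau_se=tau_se,
        p_hat=params.p,
        p_se=p_se,
        loglik=-best.fun,
        converged=True,
        se_available=se_available,
        vcov_unconstrained=vcov,
        n_individuals=histories.n_individuals,
        n_dropped_final_year=n_dropped,
        messages=messages,
    )


def filter_by_recapture(fit: CJSFit, lower: float = 0.10, upper: float = 0.90) -> list[str]:
    """Sites whose recapture estimate lies strictly inside (lower, upper).

    Estimates at or beyond the bounds are considered unrealistically
    extreme and the site is excluded from the species-specific
    analysis. The quoted bounds are exclusive except that a value equal
    to a bound is *retained* (the exclusion rule is strictly `<` / `>`).
    """
    if not fit.converged:
        raise ValueError("recapture filter requires a converged fit")
    retained = []
    for code, p in zip(fit.site_codes, fit.p_hat):
        if p < lower or p > upper:
            logger.info("%s/%s: site %s excluded (p=%.3f)", fit.scheme, fit.species, code, p)
        else:
            retained.append(code)
    return retained


def filter_by_survival_se(
    fit: CJSFit, lower: float = 0.01, upper: float = 0.25
) -> np.ndarray:
    """Boolean mask over intervals whose survival SE is strictly inside
    (lower, upper).

    Very small SEs signal degenerate precision, very large ones an
    unreliable estimate; both are dropped, per species and scheme.
    """
    if not fit.se_available:
        raise DataError("survival SEs unavailable for this fit")
    se = np.asarray(fit.phi_se, dtype=float)
    mask = (se > lower) & (se < upper) & np.isfinite(se)
    for t in np.nonzero(~mask)[0]:
        logger.info(
            "%s/%s: interval %d (%d->%d) dropped (SE=%.4f)",
            fit.scheme,
            fit.species,
            t,
            fit.years[t],
            fit.years[t + 1],
            se[t],
        )
    return mask
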