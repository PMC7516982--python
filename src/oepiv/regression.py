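"""Right-censored log-location-scale regression with LOEPIV errors.

Model: y_i = beta'x_i + sigma * z_i, with z_i distributed as the standardized
LOEPIV error (shapes lam, alpha) and y_i = log(min(failure, censoring) time).
The censored log-likelihood, with r = sum(tau_i) events and z_i = (y_i -
beta'x_i)/sigma, is

    l = r[log lam + log alpha - log sigma] + n*lam
        + sum_i tau_i [z_i + (alpha-1) log(1+e^{z_i})]
        - lam sum_i (1+e^{z_i})^alpha,

where the censored contribution lam - lam(1+e^{z_i})^alpha is used in its
simplified algebraic form.  Parameters are packed as
theta = (beta_1..beta_p, sigma, lam, alpha); the fit optimizes over
(beta, log sigma, log lam, log alpha) with the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .logcore import LOEPIVParams, loepiv_logsf
from .mle import information_criteria, numeric_hessian

__all__ = [
    "CensoredSample",
    "RegressionFit",
    "JackknifeFit",
    "censored_loglik",
    "censored_score",
    "fit_ml",
    "fit_jackknife",
    "leave_one_out_estimates",
    "predict_survival",
]


@dataclass(frozen=True)
class CensoredSample:
    """Log-times y, event indicators tau (1=event, 0=censored), design matrix X.

    X must carry the intercept as its first column.  Identifiability of
    (beta, sigma, lam, alpha) requires at least p+3 observed events.
    """

    y: np.ndarray
    tau: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float).ravel()
        tau = np.asarray(self.tau, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] != y.size or tau.size != y.size:
            raise ValueError(
                f"length mismatch: y has {y.size} rows, tau {tau.size}, X {X.shape[0]}"
            )
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise ValueError(f"y contains a non-finite value at row {bad}")
        if not np.all(np.isin(tau, (0.0, 1.0))):
            bad = int(np.flatnonzero(~np.isin(tau, (0.0, 1.0)))[0])
            raise ValueError(f"tau must be 0/1; offending row {bad}")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "tau", tau.astype(int))
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def r(self) -> int:
        return int(self.tau.sum())

    def drop(self, i: int) -> "CensoredSample":
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return CensoredSample(self.y[keep], self.tau[keep], self.X[keep])

    def param_names(self) -> list[str]:
        return [f"beta{j}" for j in range(self.p)] + ["sigma", "lam", "alpha"]


@dataclass
class RegressionFit:
    beta: np.ndarray
    sigma: float
    lam: float
    alpha: float
    loglik: float
    covariance: np.ndarray | None
    converged: bool
    boundary: bool  # sigma/lam/alpha collapsed to a degenerate ridge
    n_obs: int
    n_events: int
    aic: float
    caic: float
    bic: float
    param_names: list[str]
    _std_errors: np.ndarray | None = field(default=None, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.beta, [self.sigma, self.lam, self.alpha]])

    @property
    def std_errors(self) -> np.ndarray:
        if not self.converged:
            raise RuntimeError("fit did not converge; standard errors are undefined")
        if self._std_errors is None:
            raise RuntimeError("covariance unavailable (singular or indefinite Hessian)")
        return self._std_errors

    @property
    def p_values(self) -> np.ndarray:
        """Two-sided Wald p-values against the asymptotic normal reference."""
        z = self.theta / self.std_errors
        return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class JackknifeFit:
    pseudo_values: np.ndarray  # n x (p+3)
    estimate: np.ndarray
    std_errors: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    param_names: list[str]
    n_failed: int = 0


def _unpack_theta(theta, p):
    theta = np.asarray(theta, dtype=float)
    if theta.size != p + 3:
        raise ValueError(f"theta must have length p+3 = {p + 3}, got {theta.size}")
    beta = theta[:p]
    sigma, lam, alpha = theta[p], theta[p + 1], theta[p + 2]
    if sigma <= 0 or lam <= 0 or alpha <= 0:
        raise ValueError("sigma, lam, alpha must be strictly positive")
    return beta, sigma, lam, alpha


def censored_loglik(sample: CensoredSample, theta) -> float:
    beta, sigma, lam, alpha = _unpack_theta(theta, sample.p)
    z = (sample.y - sample.X @ beta) / sigma
    s = np.logaddexp(0.0, z)  # log(1 + e^z)
    with np.errstate(over="ignore"):
        em = np.expm1(alpha * s)  # (1+e^z)^alpha - 1
    r = sample.r
    return float(
        r * (np.log(lam) + np.log(alpha) - np.log(sigma))
        + (sample.tau * (z + (alpha - 1.0) * s)).sum()
        - lam * em.sum()
    )


def censored_score(sample: CensoredSample, theta) -> np.ndarray:
    """Analytic gradient of censored_loglik with respect to theta."""
    beta, sigma, lam, alpha = _unpack_theta(theta, sample.p)
    tau = sample.tau
    z = (sample.y - sample.X @ beta) / sigma
    s = np.logaddexp(0.0, z)
    w = np.exp(z - s)  # e^z / (1+e^z)
    with np.errstate(over="ignore"):
        A = np.exp(alpha * s)  # (1+e^z)^alpha
    r = sample.r
    gz = tau * (1.0 + (alpha - 1.0) * w) - lam * alpha * A * w
    d_beta = -(sample.X.T @ gz) / sigma
    d_sigma = (-r - (gz * z).sum()) / sigma
    d_lam = r / lam - np.expm1(alpha * s).sum()
    d_alpha = r / alpha + (tau * s).sum() - lam * (A * s).sum()
    return np.concatenate([d_beta, [d_sigma, d_lam, d_alpha]])


def _default_init(sample: CensoredSample) -> np.ndarray:
    beta0, *_ = np.linalg.lstsq(sample.X, sample.y, rcond=None)
    resid = sample.y - sample.X @ beta0
    sigma0 = float(np.std(resid[sample.tau == 1])) if sample.r > 1 else 1.0
    sigma0 = max(sigma0, 1e-2)
    return np.concatenate([beta0, [sigma0, 1.0, 1.0]])


def fit_ml(sample: CensoredSample, init=None, *, max_restarts: int = 5,
           gtol: float = 1e-8) -> RegressionFit:
    """ML fit of (beta, sigma, lam, alpha) by quasi-Newton on the transformed
    scale (positive parameters log-transformed), with Newton polish and
    delta-method covariance."""
    p, n, r = sample.p, sample.n, sample.r
    if np.linalg.matrix_rank(sample.X) < p:
        raise ValueError("design matrix X is rank deficient")
    if r < p + 3:
        raise ValueError(
            f"identifiability requires at least p+3 = {p + 3} events; sample has {r}"
        )

    def to_theta(u):
        # cap positive parameters at e^+-40 to keep line-search trials finite
        return np.concatenate([u[:p], np.exp(np.clip(u[p:], -40.0, 40.0))])

    def negloglik(u):
        try:
            val = -censored_loglik(sample, to_theta(u))
        except (ValueError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    def neggrad(u):
        theta = to_theta(u)
        with np.errstate(all="ignore"):
            g = censored_score(sample, theta)
        g[p:] *= theta[p:]  # chain rule through the log transform
        return np.nan_to_num(-g, nan=0.0, posinf=1e10, neginf=-1e10)

    theta0 = _default_init(sample) if init is None else np.asarray(init, dtype=float)
    u0 = np.concatenate([theta0[:p], np.log(theta0[p:])])

    rng = np.random.default_rng(54321)
    best = None
    for attempt in range(max_restarts + 1):
        start = u0.copy()
        if attempt > 0:
            start[p:] += rng.normal(scale=0.4, size=3)
            start[0] += rng.normal(scale=0.5)
        res = optimize.minimize(negloglik, start, jac=neggrad, method="BFGS",
                                options={"gtol": gtol, "maxiter": 1000})
        gnorm = float(np.max(np.abs(res.jac)))
        ok = np.isfinite(res.fun) and (res.success or gnorm < 1e-5 * max(1.0, abs(res.fun)))
        if ok:
            if best is None or res.fun < best.fun:
                best = res
            break
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res

    u_hat = best.x
    # Newton polish
    for _ in range(5):
        g = neggrad(u_hat)
        if np.max(np.abs(g)) < 1e-9 * max(1.0, abs(best.fun)):
            break
        H = numeric_hessian(negloglik, u_hat)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        f_cur = negloglik(u_hat)
        scale, accepted = 1.0, False
        for _ls in range(6):
            cand = u_hat - scale * step
            if negloglik(cand) < f_cur:
                u_hat, accepted = cand, True
                break
            scale *= 0.5
        if not accepted:
            break

    theta_hat = to_theta(u_hat)
    loglik = -negloglik(u_hat)
    gfin = np.max(np.abs(neggrad(u_hat)))
    # as for the uncensored family, the likelihood sup can sit on a boundary
    # (sigma, alpha -> 0, or alpha -> 0 with lam -> inf); such termini are
    # kept, flagged, uncovarianced
    boundary = bool(np.isfinite(loglik) and loglik > -1e11
                    and (float(np.min(theta_hat[p:])) < 1e-5
                         or float(np.max(theta_hat[p:])) > 1e10))
    interior = bool(not boundary and np.isfinite(loglik) and loglik > -1e11
                    and gfin < 1e-4 * max(1.0, abs(loglik)))
    converged = interior or boundary

    cov = None
    se = None
    if interior:
        H_u = numeric_hessian(negloglik, u_hat)
        H_u = 0.5 * (H_u + H_u.T)
        try:
            if np.all(np.linalg.eigvalsh(H_u) > 0):
                cov_u = np.linalg.inv(H_u)
                D = np.ones(p + 3)
                D[p:] = theta_hat[p:]
                cov = cov_u * np.outer(D, D)
                se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            pass

    k = p + 3
    aic, caic, bic = information_criteria(loglik, k, n)
    return RegressionFit(
        beta=theta_hat[:p], sigma=float(theta_hat[p]), lam=float(theta_hat[p + 1]),
        alpha=float(theta_hat[p + 2]), loglik=loglik, covariance=cov,
        converged=converged, boundary=boundary, n_obs=n, n_events=r,
        aic=aic, caic=caic, bic=bic,
        param_names=sample.param_names(), _std_errors=se,
    )


def leave_one_out_estimates(sample: CensoredSample, full_fit: RegressionFit):
    """Refit with each row deleted, warm-started at the full-sample estimate.

    Returns (thetas, ok) where thetas is an n x (p+3) array of deletion
    estimates (rows of failed refits hold the full-sample estimate) and ok a
    boolean mask of successful refits.
    """
    n = sample.n
    thetas = np.tile(full_fit.theta, (n, 1))
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        sub = sample.drop(i)
        try:
            fit_i = fit_ml(sub, init=full_fit.theta, max_restarts=2)
        except ValueError:
            continue
        if fit_i.converged and not fit_i.boundary:
            thetas[i] = fit_i.theta
            ok[i] = True
    return thetas, ok


def fit_jackknife(sample: CensoredSample, full_fit: RegressionFit | None = None,
                  *, z_crit: float = 1.96) -> JackknifeFit:
    """Jackknife estimation: pseudo-values theta~_i = n*theta^ - (n-1)*theta^_(-i),
    estimate = mean of pseudo-values, SE = sqrt(sum (theta~_i - mean)^2 / (n(n-1))).

    95% intervals are estimate +- 1.96*SE, floored at 0 for the positive-
    constrained components (sigma, lam, alpha).  Failed leave-one-out refits
    are excluded and counted.
    """
    if full_fit is None:
        full_fit = fit_ml(sample)
    if not full_fit.converged or full_fit.boundary:
        raise RuntimeError("full-sample ML fit did not converge to an interior "
                           "optimum; jackknife unavailable")
    n, p = sample.n, sample.p
    if n < p + 4:
        raise ValueError("jackknife requires n >= p+4")
    thetas, ok = leave_one_out_estimates(sample, full_fit)
    m = int(ok.sum())
    if m == 0:
        raise RuntimeError("all leave-one-out refits failed")
    pseudo = n * full_fit.theta[None, :] - (n - 1) * thetas[ok]
    estimate = pseudo.mean(axis=0)
    se = np.sqrt(((pseudo - estimate) ** 2).sum(axis=0) / (m * (m - 1)))
    lo = estimate - z_crit * se
    hi = estimate + z_crit * se
    lo[p:] = np.maximum(lo[p:], 0.0)  # positive components floored at 0
    return JackknifeFit(pseudo_values=pseudo, estimate=estimate, std_errors=se,
                        ci_lower=lo, ci_upper=hi, param_names=sample.param_names(),
                        n_failed=n - m)


def predict_survival(fit: RegressionFit, x_new, y):
    """S(y | x) = e^lam exp(-lam (1 + e^{(y - beta'x)/sigma})^alpha)."""
    x_new = np.asarray(x_new, dtype=float).ravel()
    if x_new.size != fit.beta.size:
        raise ValueError(f"x_new has {x_new.size} entries; model expects {fit.beta.size}")
    mu = float(x_new @ fit.beta)
    params = LOEPIVParams(lam=fit.lam, alpha=fit.alpha, sigma=fit.sigma, mu=mu)
    return np.exp(loepiv_logsf(y, params))
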