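"""Case-deletion influence measures and residual analysis for LOEPIV regression.

Influence is measured by the generalized Cook distance

    GD_i = (theta^_(-i) - theta^)' J(theta^) (theta^_(-i) - theta^),

with J the observed information of the censored log-likelihood at the
full-sample estimate (constrained parameter scale), and by the likelihood
distance LD_i = 2[l(theta^) - l(theta^_(-i))], where l is always the
full-data log-likelihood.

Residuals follow the martingale / deviance pair standard in survival
analysis: rM_i = delta_i + log S(y_i), rD_i = sign(rM_i) *
sqrt(-2[rM_i + delta_i log(delta_i - rM_i)]).  Under a well-specified model
the deviance residuals are approximately standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logcore import error_rvs
from .mle import numeric_hessian
from .regression import (CensoredSample, RegressionFit, censored_loglik,
                         fit_ml, leave_one_out_estimates)

__all__ = [
    "InfluenceReport",
    "ResidualSet",
    "generalized_cook",
    "likelihood_distance",
    "influence_report",
    "martingale_residuals",
    "deviance_residuals",
    "residual_set",
    "KaplanMeier",
    "km_estimator",
    "simulated_envelope",
]


@dataclass
class InfluenceReport:
    gd: np.ndarray
    ld: np.ndarray
    flagged: np.ndarray  # indices exceeding the mean + 3 sd rule on GD or LD
    info_indefinite: bool = False
    n_failed: int = 0


@dataclass
class ResidualSet:
    martingale: np.ndarray
    deviance: np.ndarray
    censor_indicator: np.ndarray


def _loglik_theta(sample):
    def f(theta):
        try:
            return censored_loglik(sample, theta)
        except ValueError:
            return -np.inf
    return f


def generalized_cook(sample: CensoredSample, full_fit: RegressionFit,
                     leave_one_out_fits: np.ndarray):
    """GD_i for each deletion estimate, in the observed-information metric.

    Returns (gd, indefinite_flag).  ``leave_one_out_fits`` is the n x (p+3)
    matrix of deletion estimates (as from leave_one_out_estimates).
    """
    theta_hat = full_fit.theta
    J = -numeric_hessian(_loglik_theta(sample), theta_hat)
    J = 0.5 * (J + J.T)
    if not np.all(np.isfinite(J)):
        # degenerate (boundary) optimum: information is not estimable
        return np.full(sample.n, np.nan), True
    try:
        indefinite = bool(np.any(np.linalg.eigvalsh(J) <= 0))
    except np.linalg.LinAlgError:
        return np.full(sample.n, np.nan), True
    d = np.asarray(leave_one_out_fits) - theta_hat[None, :]
    gd = np.einsum("ij,jk,ik->i", d, J, d)
    return gd, indefinite


def likelihood_distance(sample: CensoredSample, full_fit: RegressionFit,
                        leave_one_out_fits: np.ndarray) -> np.ndarray:
    """LD_i = 2[l(theta^) - l(theta^_(-i))], full-data log-likelihood both times."""
    ll = _loglik_theta(sample)
    l_hat = ll(full_fit.theta)
    return np.array([2.0 * (l_hat - ll(t)) for t in np.asarray(leave_one_out_fits)])


def influence_report(sample: CensoredSample, full_fit: RegressionFit,
                     leave_one_out_fits: np.ndarray | None = None,
                     ok: np.ndarray | None = None) -> InfluenceReport:
    """GD and LD for every case plus a reproducible flag rule (mean + 3 sd)."""
    if leave_one_out_fits is None:
        leave_one_out_fits, ok = leave_one_out_estimates(sample, full_fit)
    if ok is None:
        ok = np.ones(sample.n, dtype=bool)
    gd, indef = generalized_cook(sample, full_fit, leave_one_out_fits)
    ld = likelihood_distance(sample, full_fit, leave_one_out_fits)
    gd = np.where(ok, gd, np.nan)
    ld = np.where(ok, ld, np.nan)

    def _exceeds(v):
        m, s = np.nanmean(v), np.nanstd(v)
        return np.nan_to_num(v, nan=-np.inf) > m + 3.0 * s

    flagged = np.flatnonzero(_exceeds(gd) | _exceeds(ld))
    return InfluenceReport(gd=gd, ld=ld, flagged=flagged, info_indefinite=indef,
                           n_failed=int((~ok).sum()))


def martingale_residuals(sample: CensoredSample, fit: RegressionFit) -> np.ndarray:
    """rM_i = delta_i + log S(y_i; theta^), in (-inf, 1]."""
    from .logcore import error_logsf
    z = (sample.y - sample.X @ fit.beta) / fit.sigma
    return sample.tau + error_logsf(z, fit.lam, fit.alpha)


def deviance_residuals(sample: CensoredSample, fit: RegressionFit) -> np.ndarray:
    """Signed square-root transform of the martingale residual.

    Events: sign(rM) sqrt(-2[rM + log(1 - rM)]); censored: -sqrt(-2 rM)
    (rM <= 0 there).  The bracket is non-positive by the inequality
    x + log(1-x) <= 0, so tiny negative arguments are clipped at 0; a
    materially negative argument raises with the case index.
    """
    rm = martingale_residuals(sample, fit)
    delta = sample.tau.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = np.where(delta == 1.0, -2.0 * (rm + np.log1p(-rm)), -2.0 * rm)
    bad = np.flatnonzero(~np.isfinite(inner) | (inner < -1e-8))
    if bad.size:
        raise FloatingPointError(
            f"deviance residual undefined at case {int(bad[0])} (rM={rm[bad[0]]})"
        )
    return np.sign(rm) * np.sqrt(np.clip(inner, 0.0, None))


def residual_set(sample: CensoredSample, fit: RegressionFit) -> ResidualSet:
    return ResidualSet(
        martingale=martingale_residuals(sample, fit),
        deviance=deviance_residuals(sample, fit),
        censor_indicator=sample.tau.copy(),
    )


class KaplanMeier:
    """Right-continuous product-limit survival estimate."""

    def __init__(self, event_times: np.ndarray, survival: np.ndarray):
        self.event_times = event_times
        self.survival = survival

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        steps = np.concatenate([[1.0], self.survival])
        return steps[idx]


def km_estimator(times, status) -> KaplanMeier:
    """Kaplan-Meier estimate from raw times and 1=event/0=censored status."""
    times = np.asarray(times, dtype=float).ravel()
    status = np.asarray(status).ravel().astype(int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    t_sorted, s_sorted = times[order], status[order]
    uniq = np.unique(t_sorted[s_sorted == 1])
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(t_sorted >= t)
        d = np.sum((t_sorted == t) & (s_sorted == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return KaplanMeier(uniq, np.asarray(surv))


def _censoring_sampler(sample: CensoredSample):
    """Sampler for censoring thresholds on the y-scale.

    The censoring law is estimated by the reverse Kaplan-Meier (censorings
    as events); the unreached upper tail keeps its mass at +inf (no
    censoring).  Returns None when the sample is fully uncensored.
    """
    if np.all(sample.tau == 1):
        return None
    km = km_estimator(np.exp(sample.y - sample.y.min() + 1.0), 1 - sample.tau)
    support = np.log(km.event_times) + sample.y.min() - 1.0
    surv = np.concatenate([[1.0], km.survival])
    pmass = surv[:-1] - surv[1:]
    tail = surv[-1]
    values = np.concatenate([support, [np.inf]])
    probs = np.concatenate([pmass, [tail]])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()

    def draw(rng, size):
        return rng.choice(values, size=size, replace=True, p=probs)

    return draw


def simulated_envelope(sample: CensoredSample, fit: RegressionFit,
                       n_sim: int = 100, band: tuple = (2.5, 97.5),
                       seed=None):
    """Simulated envelope for the normal probability plot of deviance residuals.

    Atkinson-style: simulate n_sim datasets from the fitted model (same X;
    censoring thresholds drawn from the reverse-Kaplan-Meier estimate of the
    censoring law), refit each, and take per-rank percentiles of the ordered
    deviance residuals.  Returns (lower, upper, n_failed).
    """
    if n_sim < 19:
        raise ValueError("n_sim must be at least 19")
    rng = np.random.default_rng(seed)
    n = sample.n
    draw_c = _censoring_sampler(sample)
    paths = []
    failed = 0
    for _ in range(n_sim):
        z = error_rvs(n, fit.lam, fit.alpha, seed=rng)
        y_star = sample.X @ fit.beta + fit.sigma * z
        tau_star = np.ones(n, dtype=int)
        if draw_c is not None:
            c = draw_c(rng, n)
            tau_star = (y_star <= c).astype(int)
            y_star = np.minimum(y_star, c)
        try:
            sim_sample = CensoredSample(y_star, tau_star, sample.X)
            sim_fit = fit_ml(sim_sample, init=fit.theta, max_restarts=2)
            if not sim_fit.converged or sim_fit.boundary:
                raise RuntimeError
            paths.append(np.sort(deviance_residuals(sim_sample, sim_fit)))
        except (ValueError, RuntimeError, FloatingPointError):
            failed += 1
    if not paths:
        raise RuntimeError("all envelope simulations failed to refit")
    paths = np.vstack(paths)
    lower = np.percentile(paths, band[0], axis=0)
    upper = np.percentile(paths, band[1], axis=0)
    return lower, upper, failed
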