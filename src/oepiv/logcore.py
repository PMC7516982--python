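"""The log-OEPIV (LOEPIV) distribution and its standardized error law.

If X ~ OEPIV(lam, a, theta, alpha) then Y = log X follows the LOEPIV
distribution with scale sigma = a, location mu = log(theta) and the same
shape parameters (lam, alpha).  With z = (y - mu)/sigma,

    f(y) = (lam*alpha/sigma) e^lam e^z (1+e^z)^(alpha-1) exp(-lam (1+e^z)^alpha)
    S(y) = e^lam exp(-lam (1+e^z)^alpha)

This is the error distribution of the log-location-scale regression model
y = beta'x + sigma*z.  The standardized variable z (sigma=1, mu=0) is exposed
separately as the error_* family, parameterized by (lam, alpha) only.

(1+e^z)^alpha is always computed as exp(alpha * softplus(z)) so optimizer
excursions to z of order +-40 stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .core import OEPIVParams

__all__ = [
    "LOEPIVParams",
    "loepiv_logpdf",
    "loepiv_pdf",
    "loepiv_cdf",
    "loepiv_sf",
    "loepiv_logsf",
    "loepiv_hf",
    "loepiv_quantile",
    "loepiv_median",
    "loepiv_mode",
    "loepiv_rvs",
    "loepiv_mgf",
    "error_logpdf",
    "error_pdf",
    "error_sf",
    "error_cdf",
    "error_quantile",
    "error_rvs",
    "from_oepiv",
    "to_oepiv",
]


@dataclass(frozen=True)
class LOEPIVParams:
    """Log-scale parameterization: shapes lam, alpha; scale sigma; location mu."""

    lam: float
    alpha: float
    sigma: float
    mu: float

    def __post_init__(self):
        for name in ("lam", "alpha", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"LOEPIV parameter {name!r} must be positive, got {v!r}")
            object.__setattr__(self, name, float(v))
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        object.__setattr__(self, "mu", float(self.mu))

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "alpha": self.alpha, "sigma": self.sigma, "mu": self.mu}

    @classmethod
    def from_dict(cls, d: dict) -> "LOEPIVParams":
        return cls(float(d["lambda"]), float(d["alpha"]), float(d["sigma"]), float(d["mu"]))


def from_oepiv(params: OEPIVParams) -> LOEPIVParams:
    """Parameter mapping for Y = log X: sigma = a, mu = log(theta)."""
    return LOEPIVParams(lam=params.lam, alpha=params.alpha, sigma=params.a,
                        mu=float(np.log(params.theta)))


def to_oepiv(params: LOEPIVParams) -> OEPIVParams:
    return OEPIVParams(lam=params.lam, a=params.sigma, theta=float(np.exp(params.mu)),
                       alpha=params.alpha)


# ---------------------------------------------------------------------------
# standardized error variable (lam, alpha only)

def _softplus(z):
    return np.logaddexp(0.0, z)


def error_logpdf(z, lam: float, alpha: float):
    z = np.asarray(z, dtype=float)
    s = _softplus(z)
    with np.errstate(over="ignore"):
        return np.log(lam * alpha) + z + (alpha - 1.0) * s - lam * np.expm1(alpha * s)


def error_pdf(z, lam: float, alpha: float):
    return np.exp(error_logpdf(z, lam, alpha))


def error_logsf(z, lam: float, alpha: float):
    s = _softplus(np.asarray(z, dtype=float))
    with np.errstate(over="ignore"):
        return -lam * np.expm1(alpha * s)


def error_sf(z, lam: float, alpha: float):
    return np.exp(error_logsf(z, lam, alpha))


def error_cdf(z, lam: float, alpha: float):
    return -np.expm1(error_logsf(z, lam, alpha))


def error_quantile(p, lam: float, alpha: float):
    """Closed-form inverse: z = log[(1 - log(1-p)/lam)^(1/alpha) - 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")
    s = -np.log1p(-p) / lam
    inner = np.expm1(np.log1p(s) / alpha)
    with np.errstate(divide="ignore"):
        return np.log(inner)


def error_rvs(n: int, lam: float, alpha: float, seed=None) -> np.ndarray:
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return error_quantile(rng.uniform(size=n), lam, alpha)


# ---------------------------------------------------------------------------
# full location-scale family

def loepiv_logpdf(y, params: LOEPIVParams):
    z = (np.asarray(y, dtype=float) - params.mu) / params.sigma
    return error_logpdf(z, params.lam, params.alpha) - np.log(params.sigma)


def loepiv_pdf(y, params: LOEPIVParams):
    return np.exp(loepiv_logpdf(y, params))


def loepiv_logsf(y, params: LOEPIVParams):
    z = (np.asarray(y, dtype=float) - params.mu) / params.sigma
    return error_logsf(z, params.lam, params.alpha)


def loepiv_sf(y, params: LOEPIVParams):
    return np.exp(loepiv_logsf(y, params))


def loepiv_cdf(y, params: LOEPIVParams):
    return -np.expm1(loepiv_logsf(y, params))


def loepiv_hf(y, params: LOEPIVParams):
    """Hazard (lam*alpha/sigma) e^z (1+e^z)^(alpha-1)."""
    z = (np.asarray(y, dtype=float) - params.mu) / params.sigma
    s = _softplus(z)
    return np.exp(np.log(params.lam * params.alpha / params.sigma) + z
                  + (params.alpha - 1.0) * s)


def loepiv_quantile(p, params: LOEPIVParams):
    return params.mu + params.sigma * error_quantile(p, params.lam, params.alpha)


def loepiv_median(params: LOEPIVParams) -> float:
    """sigma * log[(1 + log2/lam)^(1/alpha) - 1] + mu."""
    return float(loepiv_quantile(0.5, params))


def loepiv_rvs(n: int, params: LOEPIVParams, seed=None) -> np.ndarray:
    return params.mu + params.sigma * error_rvs(n, params.lam, params.alpha, seed)


def loepiv_mode(params: LOEPIVParams) -> float:
    """Maximizer of the density, found numerically in the standardized scale."""
    lam, alpha = params.lam, params.alpha
    # the log-density in z is smooth and unimodal-ish; bracket widely
    res = optimize.minimize_scalar(lambda z: -error_logpdf(z, lam, alpha),
                                   bracket=(-5.0, 0.0, 5.0), method="brent",
                                   options={"xtol": 1e-12})
    # guard against a bad bracket: refine by grid + bounded search
    grid = np.linspace(-60.0, 60.0, 2001)
    lp = error_logpdf(grid, lam, alpha)
    i = int(np.argmax(lp))
    if lp[i] > -res.fun + 1e-12:
        res = optimize.minimize_scalar(
            lambda z: -error_logpdf(z, lam, alpha),
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded", options={"xatol": 1e-12})
    return float(params.mu + params.sigma * res.x)


def loepiv_mgf(t: float, params: LOEPIVParams) -> float:
    """E[e^{tY}] by quadrature; equals E[X^t] for the parent OEPIV variate.

    The right tail always integrates (stretched-exponential); the left tail
    requires t > -1/sigma, otherwise the integral diverges and +inf is
    returned.
    """
    if t == 0:
        return 1.0
    if t <= -1.0 / params.sigma:
        return float(np.inf)

    def integrand(u):
        # substitute y = Q(u): E[e^{tY}] = int_0^1 exp(t * Q(u)) du
        return float(np.exp(t * loepiv_quantile(u, params)))

    val, err = integrate.quad(integrand, 0.0, 1.0, limit=200, points=[1e-8, 1 - 1e-8])
    if not np.isfinite(val):
        return float(np.inf)
    return float(val)
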