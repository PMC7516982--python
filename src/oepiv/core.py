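"""The odds exponential-Pareto IV (OEPIV) distribution.

The OEPIV law arises from the T-X construction: the Pareto IV odds ratio
F/(1-F) is fed through a unit-rate exponential generator, giving the survival
function

    S(x) = exp(-lam * [(1 + (x/theta)^(1/a))^alpha - 1]),   x > 0,

with shape parameters ``lam, alpha > 0``, scale ``theta > 0`` and Pareto
inequality parameter ``a > 0``.  Special cases: ``alpha = 1`` reduces to a
Weibull with shape ``1/a`` and scale ``theta * lam^(-a)``; ``(1, 1, 1, 1)``
is the unit exponential.

All power terms are evaluated in log space (``log1p``/``expm1`` identities)
so that large ``(x/theta)^(1/a)`` never overflows before the final
exponential is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "OEPIVParams",
    "MomentSummary",
    "oepiv_logpdf",
    "oepiv_pdf",
    "oepiv_cdf",
    "oepiv_sf",
    "oepiv_logsf",
    "oepiv_hf",
    "oepiv_quantile",
    "oepiv_median",
    "oepiv_rvs",
    "oepiv_mode",
    "oepiv_raw_moment",
    "oepiv_moment_series",
    "oepiv_moment_summary",
    "order_statistic_pdf",
    "renyi_entropy",
]


@dataclass(frozen=True)
class OEPIVParams:
    """Parameter vector (lam, a, theta, alpha); all strictly positive."""

    lam: float
    a: float
    theta: float
    alpha: float

    def __post_init__(self):
        for name in ("lam", "a", "theta", "alpha"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"OEPIV parameter {name!r} must be a positive finite real, got {v!r}"
                )
            object.__setattr__(self, name, float(v))

    def as_array(self) -> np.ndarray:
        return np.array([self.lam, self.a, self.theta, self.alpha], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "OEPIVParams":
        lam, a, theta, alpha = np.asarray(arr, dtype=float)
        return cls(lam, a, theta, alpha)

    def to_dict(self) -> dict:
        """Flat key-value form (keys: lambda, a, theta, alpha)."""
        return {"lambda": self.lam, "a": self.a, "theta": self.theta, "alpha": self.alpha}

    @classmethod
    def from_dict(cls, d: dict) -> "OEPIVParams":
        return cls(float(d["lambda"]), float(d["a"]), float(d["theta"]), float(d["alpha"]))


@dataclass(frozen=True)
class MomentSummary:
    mean: float
    variance: float
    skewness: float
    excess_kurtosis: float

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


def _validate_x(x, allow_zero=True):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if not allow_zero and np.any(x == 0):
        raise ValueError("x must be strictly positive")
    return x


def _log_h(x, params: OEPIVParams):
    """log(1 + (x/theta)^(1/a)), stable for arbitrarily large x.

    Returns -inf-safe values: x = 0 gives 0.
    """
    with np.errstate(divide="ignore"):
        logt = np.log(x / params.theta) / params.a  # -inf at x = 0
    # log(1 + e^logt) without overflow
    return np.logaddexp(0.0, logt)


def oepiv_logpdf(x, params: OEPIVParams):
    x = _validate_x(x)
    lam, a, theta, alpha = params.lam, params.a, params.theta, params.alpha
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    pos = x > 0
    xp = x[pos]
    logh = _log_h(xp, params)
    with np.errstate(over="ignore"):
        # lam + ... - lam*h^alpha collapses to -lam*expm1(alpha*logh)
        out[pos] = (
            np.log(lam * alpha / (a * theta))
            + (1.0 / a - 1.0) * np.log(xp / theta)
            - lam * np.expm1(alpha * logh)
            + (alpha - 1.0) * logh
        )
    if np.any(~pos):
        # analytic limit at the origin
        if a < 1:  # (x/theta)^(1/a - 1) -> 0
            out[~pos] = -np.inf
        elif a == 1:
            out[~pos] = np.log(lam * alpha / (a * theta))
        else:  # density diverges at 0
            out[~pos] = np.inf
    return out[0] if scalar else out


def oepiv_pdf(x, params: OEPIVParams):
    """Density of the OEPIV distribution; x = 0 returns the analytic limit."""
    return np.exp(oepiv_logpdf(x, params))


def oepiv_logsf(x, params: OEPIVParams):
    x = _validate_x(x)
    logh = _log_h(np.asarray(x, dtype=float), params)
    with np.errstate(over="ignore"):
        return -params.lam * np.expm1(params.alpha * logh)


def oepiv_sf(x, params: OEPIVParams):
    return np.exp(oepiv_logsf(x, params))


def oepiv_cdf(x, params: OEPIVParams):
    return -np.expm1(oepiv_logsf(x, params))


def oepiv_hf(x, params: OEPIVParams):
    """Hazard lam*alpha/(a*theta) (x/theta)^(1/a-1) (1+(x/theta)^(1/a))^(alpha-1)."""
    x = _validate_x(x, allow_zero=False)
    lam, a, theta, alpha = params.lam, params.a, params.theta, params.alpha
    logh = _log_h(x, params)
    return np.exp(
        np.log(lam * alpha / (a * theta))
        + (1.0 / a - 1.0) * np.log(x / theta)
        + (alpha - 1.0) * logh
    )


def oepiv_quantile(p, params: OEPIVParams):
    """Inverse CDF: theta * [(1 - log(1-p)/lam)^(1/alpha) - 1]^a for p in [0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("p must lie in [0, 1)")
    s = -np.log1p(-p) / params.lam  # -log(1-p)/lam >= 0
    inner = np.expm1(np.log1p(s) / params.alpha)  # (1+s)^(1/alpha) - 1
    return params.theta * inner**params.a


def oepiv_median(params: OEPIVParams) -> float:
    return float(oepiv_quantile(0.5, params))


def oepiv_rvs(n: int, params: OEPIVParams, seed=None) -> np.ndarray:
    """n inverse-CDF draws; `seed` may be an int or a numpy Generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return oepiv_quantile(rng.uniform(size=n), params)


def oepiv_mode(params: OEPIVParams) -> float:
    """Argmax of the density: interior root of d/dx log g, else the boundary 0.

    A log-spaced grid on (0, q(0.999)] brackets the maximiser, which is then
    refined by bounded scalar minimisation of -log g; if the density is
    decreasing from the origin (or diverges there, a > 1) the boundary mode 0
    is returned.
    """
    if params.a > 1:
        return 0.0  # density diverges at the origin
    hi = float(oepiv_quantile(0.999, params))
    lo = max(hi * 1e-10, 1e-300)
    grid = np.geomspace(lo, hi, 400)
    lp = oepiv_logpdf(grid, params)
    i = int(np.argmax(lp))
    boundary_lp = oepiv_logpdf(0.0, params)
    if i == 0 and boundary_lp >= lp[0]:
        return 0.0
    a_br = grid[max(i - 1, 0)]
    b_br = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda x: -oepiv_logpdf(x, params), bounds=(a_br, b_br), method="bounded",
        options={"xatol": 1e-12},
    )
    if boundary_lp >= -res.fun:
        return 0.0
    return float(res.x)


def oepiv_raw_moment(r: int, params: OEPIVParams) -> float:
    """E[X^r] by adaptive quadrature.

    Substituting u = lam*(1+(x/theta)^(1/a))^alpha gives the smooth form
    e^lam * theta^r * int_lam^inf ((u/lam)^(1/alpha)-1)^(a r) e^-u du.
    """
    if r < 1 or int(r) != r:
        raise ValueError("r must be a positive integer")
    lam, a, theta, alpha = params.lam, params.a, params.theta, params.alpha

    def integrand(u):
        # ((u/lam)^(1/alpha) - 1)^(a r) * e^(lam - u), computed in log space
        g = np.expm1(np.log(u / lam) / alpha)
        if g <= 0:
            return 0.0
        return np.exp(a * r * np.log(g) + lam - u)

    val, err = integrate.quad(integrand, lam, np.inf, limit=200)
    if not np.isfinite(val) or (val > 0 and err > 1e-6 * max(1.0, abs(val))):
        raise RuntimeError(
            f"moment quadrature did not converge (value={val}, abserr={err})"
        )
    return float(theta**r * val)


def oepiv_moment_series(r: int, params: OEPIVParams, k_max: int = 200,
                        rtol: float = 1e-10):
    """Series form of the r-th raw moment.

    E[X^r] = sum_k C(ar, k) (-1)^k e^lam theta^r lam^(-(ar-k)/alpha)
             Gamma((ar-k)/alpha + 1, lam).

    The generalized binomial expansion need not converge when ``a*r`` is not
    an integer; the second return value is a convergence flag and callers
    must fall back to quadrature when it is False.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    lam, a, theta, alpha = params.lam, params.a, params.theta, params.alpha
    ar = a * r
    total = 0.0
    converged = False
    small_run = 0
    for k in range(k_max + 1):
        coef = special.binom(ar, k)
        if coef == 0.0 and k > ar:
            converged = True  # series terminated exactly (ar integer)
            break
        s = (ar - k) / alpha + 1.0  # shape of the upper incomplete gamma
        if s <= 0:
            # Gamma(s, lam) with s <= 0 is outside scipy's regularized form;
            # if remaining terms are still material the series is unusable.
            converged = small_run >= 2
            break
        term = (
            coef * (-1.0) ** k * np.exp(lam) * theta**r
            * lam ** (-(ar - k) / alpha)
            * special.gammaincc(s, lam) * special.gamma(s)
        )
        total += term
        if abs(term) <= rtol * max(1.0, abs(total)):
            small_run += 1
            if small_run >= 3:
                converged = True
                break
        else:
            small_run = 0
    return float(total), bool(converged)


def oepiv_moment_summary(params: OEPIVParams) -> MomentSummary:
    """Mean, variance and standardized third/fourth cumulant ratios."""
    m = [oepiv_raw_moment(r, params) for r in (1, 2, 3, 4)]
    mean = m[0]
    var = m[1] - mean**2
    mu3 = m[2] - 3 * mean * m[1] + 2 * mean**3
    mu4 = m[3] - 4 * mean * m[2] + 6 * mean**2 * m[1] - 3 * mean**4
    skew = mu3 / var**1.5
    kurt = mu4 / var**2
    return MomentSummary(mean=mean, variance=var, skewness=skew,
                         excess_kurtosis=kurt - 3.0)


def order_statistic_pdf(k: int, n: int, y, params: OEPIVParams):
    """Exact density of the k-th order statistic of an OEPIV sample of size n.

    n!/((k-1)!(n-k)!) F^(k-1) (1-F)^(n-k) f, with the combinatorial factor in
    log space.
    """
    if not (1 <= k <= n):
        raise ValueError("k must satisfy 1 <= k <= n")
    y = _validate_x(y, allow_zero=False)
    logc = special.gammaln(n + 1) - special.gammaln(k) - special.gammaln(n - k + 1)
    logsf = oepiv_logsf(y, params)
    cdf = -np.expm1(logsf)
    with np.errstate(divide="ignore"):
        logcdf = np.log(cdf)
    logf = oepiv_logpdf(y, params)
    out = logc + logf
    if k > 1:  # guard 0 * (-inf) when the factor is absent
        out = out + (k - 1) * logcdf
    if n > k:
        out = out + (n - k) * logsf
    return np.exp(out)


def renyi_entropy(params: OEPIVParams, R: float) -> float:
    """Rényi entropy (1/(1-R)) log int g(x)^R dx by adaptive quadrature."""
    if R <= 0 or R == 1:
        raise ValueError("R must be positive and different from 1")
    split = float(oepiv_quantile(0.999, params))

    def integrand(x):
        return float(np.exp(R * oepiv_logpdf(x, params)))

    v1, _ = integrate.quad(integrand, 0.0, split, limit=200)
    v2, _ = integrate.quad(integrand, split, np.inf, limit=200)
    total = v1 + v2
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError("entropy quadrature failed to produce a finite value")
    return float(np.log(total) / (1.0 - R))
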