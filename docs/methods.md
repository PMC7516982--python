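# Methods

## The distribution family

The OEPIV law composes a unit-rate exponential generator with the odds
function of the Pareto IV distribution. With shape parameters λ, α > 0,
inequality parameter a > 0 and scale θ > 0,

    S(x) = exp{−λ[(1 + (x/θ)^(1/a))^α − 1]},   x > 0.

All evaluation routines work through the two log-scale quantities
`log t = log(x/θ)/a` and `log h = log1p(e^{log t})` so that `(x/θ)^(1/a)`
never overflows before the final exponential; survival and density use the
identity λ − λh^α = −λ·expm1(α·log h). On the log scale (Y = log X,
σ = a, μ = log θ) the standardized error density is
λα e^λ e^z (1+e^z)^{α−1} exp{−λ(1+e^z)^α}, and (1+e^z)^α is always computed
as exp(α·softplus(z)), stable for z of order ±40 (the excursions quasi-Newton
optimizers actually take).

Closed forms: quantile θ[(1 − log(1−p)/λ)^{1/α} − 1]^a (and its log-scale
analogue), hence exact inverse-CDF sampling with explicit seeds — there is
no global random state anywhere in the package.

Special cases used as test oracles: (1,1,1,1) is Exp(1); α = 1 is Weibull
with shape 1/a and scale θλ^{−a} (the exponential-Pareto and odds
exponential-log-logistic forms are reparameterizations of this subfamily).

## Moments, entropy, order statistics

Raw moments are computed by adaptive quadrature of the substituted integral
E[X^r] = e^λ θ^r ∫_λ^∞ ((u/λ)^{1/α} − 1)^{ar} e^{−u} du, which is smooth on a
half-line and converges for every r (the right tail is stretched-
exponential). A binomial-series form of the same moment exists but its
generalized binomial expansion need not converge when a·r is not an integer
— and its incomplete-gamma shape argument becomes non-positive after
⌊a·r + α⌋ terms; the series implementation therefore returns an explicit
convergence flag, terminating exactly for integer a·r, and callers must fall
back to quadrature when the flag is false. Quadrature is the authoritative
implementation; the series is a cross-check.

Published tabulations of the family's mean/variance/skewness/kurtosis could
not be used as oracles: the values violate the universal moment inequality
kurtosis ≥ skewness² + 1 on several rows, so the tests assert that
inequality and the closed-form exponential/Weibull reductions instead.

Rényi entropy is computed as (1−R)^{-1} log ∫ g^R dx by quadrature split at
the 0.999 quantile. The mode search brackets on a log-spaced grid up to the
0.999 quantile and refines by bounded scalar minimization of the negative
log-density; when the density is decreasing from the origin (a ≤ 1) or
diverges there (a > 1) the boundary mode 0 is returned. The k-th order
statistic density uses the exact Beta-weighted form with log-space
combinatorial factors; its CDF (used in simulation tests) is the regularized
incomplete Beta of the parent CDF.

## Maximum likelihood

Fitting maximizes the log-likelihood over log-parameters (removing the
positivity constraints) by BFGS with the analytic score mapped through the
chain rule, followed by up to five Newton steps on a central-difference
Hessian with backtracking. With (λ, α) held fixed the quantile function is
log-linear in (log θ, a), so the empirical quartiles identify both;
initialization quantile-matches (a, θ) under two canonical shape
configurations — (λ₀, α₀) = (1, 1), the Weibull reduction, and (0.5, 0.25),
a strong-shape regime — runs both starts, and keeps the best final
likelihood (single-start BFGS occasionally converges to an inferior remote
local maximum on a flat ridge; the second basin catches these). Up to five
deterministic jittered restarts follow on failure. Fits are deterministic given data, init
and options. The covariance is the inverse observed information in the
log-parameterization mapped back by the delta method; standard errors are
the square roots of its diagonal and are refused (an error) when the fit did
not converge or the Hessian was not positive definite.

Trial parameters are capped at e^±40 during optimization and the objective
returns a large finite penalty (10^12) instead of infinities, so line
searches cannot produce NaNs.

### Boundary degeneracies

The family's likelihood supremum frequently sits on a boundary of the
parameter space rather than at an interior stationary point, especially in
small samples:

* **a, α → 0** — the distribution tends to a left-threshold Weibull-type law
  supported on x > θ; the profile likelihood increases monotonically along
  the ridge (verified numerically: the supremum is approached but never
  attained).
* **α → 0 with λ → ∞, λα fixed** — the log-logistic limit
  S(z) → (1+e^z)^{−λα}; a single gross upper outlier reliably drives the
  censored-regression MLE here, because the polynomial tail absorbs the
  outlier at enormous likelihood gain.
* **α → ∞ with location drift** — a Gumbel-type (log-Weibull) limit.

Fits whose terminus has any positive parameter below 10⁻⁵ or above 10¹⁰ are
flagged `boundary=True`: they are reported as converged (the optimizer did
find the supremum's direction, and simulation summaries must keep them to
avoid survivorship bias), but carry no covariance, and residual/jackknife/
influence computations exclude them because the fitted sub-model is
degenerate. The magnitude of a boundary terminus depends on the stopping
rule, so Monte Carlo summaries of cells with many boundary fits (e.g. the
small-sample cells of the recovery study, where up to ~60% of replicates
collapse) reflect the optimizer as much as the estimator; the n ≥ 200 cells,
where collapse is rare (< 1%), are the quantitatively meaningful ones.

### Likelihood-ratio testing

`lr_test` computes w = 2(ℓ_full − ℓ_nested) and the χ²_df upper tail. Note a
caveat for the natural test of the α = 1 subfamily: under α = 1 the
parameter λ is absorbed into the scale (θλ^{−a} on the raw scale), so the
unrestricted test H₀: α = 1 loses identifiability under the null and its
statistic is not asymptotically χ²₁ (empirical 5%-level rejection drifts to
~18% at n = 500). The package's null-calibration test therefore conditions
on λ; applied analysts comparing the full family against its α = 1
subfamily should treat the χ² p-value as approximate.

## Censored regression

The censored log-likelihood uses the algebraically simplified censored term
λ − λ(1+e^z)^α = −λ·expm1(α·softplus(z)); events contribute the full
log-density. The analytic gradient in (β, σ, λ, α) is implemented and
verified against central differences. Optimization, restarts, the Newton
polish, covariance and the boundary policy mirror the uncensored fitter.
Identifiability requires at least p + 3 events (p design columns including
the intercept); all-censored input is a reported error, never a silent fit.
Wald p-values use the asymptotic standard normal reference.

Jackknife: leave-one-out refits warm-start at the full-sample estimate;
failed or boundary refits are excluded and counted. The estimate is the mean
of the pseudo-values, SE = √(Σ(θ̃_i − θ̂*)²/(m(m−1))), and 95% intervals
are estimate ± 1.96·SE with the lower bound floored at 0 for σ, λ, α.

## Diagnostics

The generalized Cook distance uses the observed information of the censored
log-likelihood at θ̂ on the constrained parameter scale (central
differences); an indefinite or non-finite information matrix is flagged and
the distances reported as NaN rather than raised. The likelihood distance
always evaluates the full-data log-likelihood at the deletion estimates.
Cases are flagged when GD or LD exceeds its mean + 3 standard deviations — a
reproducible substitute for eyeballing index plots.

Deviance residuals carry an intrinsic positive location shift under light
censoring (mean ≈ +0.3 to +0.45 at the true parameters in the canonical
design; censored residuals pull it down): the transform symmetrizes the
martingale residual (|skewness| drops from ≈1.4 to ≈0.15) but does not
re-center it. Consequently a location-sensitive distance to the standard
normal, such as the Anderson–Darling statistic, can rank the mean-zero
martingale residuals *closer* to N(0,1) than the far more symmetric deviance
residuals — an ordering confirmed with an independent implementation
(R `survival::survreg` on a Weibull model). The defensible normality
property, asserted in the tests, is the symmetry gain and the decrease of
the per-observation distance A²/n with sample size.

Envelopes are Atkinson-style: simulate from the fitted model on the same
design matrix, censor with thresholds drawn from the reverse Kaplan–Meier
estimate of the censoring law (resampling observed censored times directly
was found to over-censor badly — realized minima are biased low), refit, and
take per-rank percentiles (default 2.5/97.5 over 100 simulations). The
min–max band of 19 simulations is a pointwise ≈90% band; full-path
containment across all ranks is a much rarer event and is not asserted.

The Kaplan–Meier utility is a direct product-limit implementation,
cross-checked against lifelines in the tests.

## Monte Carlo studies

The recovery study draws inverse-CDF samples, fits each replicate, and
reports mean estimate, bias (= mean − truth, exactly), MSE, the Monte Carlo
standard error of the MSE, and the converged/boundary counts per cell.
Summaries are over interior-optimum replicates: a boundary terminus has no
meaningful magnitude (it depends on how far the optimizer travelled along
the ridge), so including such fits would make cell means artifacts of the
stopping rule; boundary replicates are counted and reported instead. Cells
where they dominate (small n) should be read qualitatively.
Replicate seeds come from `SeedSequence` spawning, so cells are independent
streams and the whole study is reproducible from one master seed. The
canonical parameter sets are (0.3, 0.4, 0.5, 0.2) and (0.2, 0.1, 0.6, 0.15)
at sample sizes 30–500; the default replication is 2,000 (a desk-scale
reduction of the original 10,000-replicate design; the `n_reps` field raises
it). A cell with under 50% converged replicates aborts the study.

The residual study follows the canonical censored design: a single
uniform(0,1) covariate, lifetimes t = exp(β₀ + β₁x + σz) with
(λ, α, σ, β₀, β₁) = (0.3, 0.36, 0.6, −0.6, 1.0), censoring times
uniform(0, ρ). ρ is calibrated to the target censoring level by bisection on
a 10⁴-lifetime probe sample — the level E[min(t, ρ)]/ρ is monotone in ρ, so
no refitting is needed — to tolerance 0.001. Each replicate is summarized by
the Anderson–Darling statistic of both residual sets against the fully
specified standard normal.

The synthetic-data generators emulate these designs plus a transplant-
registry-like table (columns time/status/age/surgery/transplant with
LOEPIV-generated lifetimes and ≈30% censoring; a synthetic stand-in, not
real registry data). What they do not emulate: covariate measurement error,
informative censoring, ties from coarse measurement, or model
misspecification — so passing recovery tests demonstrates internal
consistency of estimator and generator, not robustness on real data.

## Known limitations

* Small-sample fits (n ≲ 50 for the distribution, n ≲ 100–150 for the
  5-parameter regression) collapse to boundary sub-models in a large
  fraction of samples; this is a property of the family, not the optimizer.
* The observed information is computed by central differences (no analytic
  Hessian); step size is relative (10⁻⁴), checked by step-halving in tests.
* The moment/mgf series forms are cross-checks with convergence flags, not
  primary implementations.
* Shannon entropy (the R → 1 limit), interval censoring, time-varying
  covariates and frailty are out of scope.
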