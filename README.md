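# oepiv

Parametric survival analysis with the **odds exponential–Pareto IV (OEPIV)
distribution**: the four-parameter lifetime law obtained by feeding the
Pareto IV odds ratio F/(1−F) through a unit-exponential generator (a T-X
construction), together with the **log-location-scale regression model**
built on its log-transform, right-censored maximum-likelihood and jackknife
estimation, case-deletion influence diagnostics, martingale/deviance residual
analysis, and a Monte Carlo harness for estimator-recovery studies.

The package is aimed at biostatisticians and reliability analysts who need a
lifetime family flexible enough to produce increasing, decreasing, and
upside-down hazards from one parameterization, with an accelerated-failure-
time style regression for censored data.

## The model

A positive lifetime X follows OEPIV(λ, a, θ, α), with shape parameters
λ, α > 0, scale θ > 0 and Pareto inequality parameter a > 0, when

```
S(x) = exp{ −λ [ (1 + (x/θ)^(1/a))^α − 1 ] },    x > 0
F(x) = 1 − S(x)
f(x) = (λα)/(aθ) e^λ (x/θ)^(1/a−1) (1 + (x/θ)^(1/a))^(α−1)
       · exp{ −λ (1 + (x/θ)^(1/a))^α }
```

Setting α = 1 gives a Weibull with shape 1/a and scale θλ^(−a); (1,1,1,1) is
the unit exponential. Y = log X follows the LOEPIV law with scale σ = a and
location μ = log θ, which supplies the error distribution of the regression
model

```
y_i = βᵀx_i + σ z_i ,   y_i = log(min(t_i, c_i)),  τ_i = 1{t_i ≤ c_i}
```

fitted by maximizing the right-censored log-likelihood
Σ τ_i log f(y_i) + Σ (1−τ_i) log S(y_i). Wald inference uses the inverse
observed information (delta method through the log-parameterization);
jackknife estimation uses leave-one-out pseudo-values
θ̃_i = nθ̂ − (n−1)θ̂₋ᵢ. Diagnostics include the generalized Cook distance
GD_i = (θ̂₋ᵢ−θ̂)ᵀ J(θ̂) (θ̂₋ᵢ−θ̂), the likelihood distance
LD_i = 2[ℓ(θ̂) − ℓ(θ̂₋ᵢ)], martingale residuals r^M_i = τ_i + log S(y_i),
deviance residuals r^D_i = sign(r^M_i)·√(−2[r^M_i + τ_i log(τ_i − r^M_i)]),
and simulated normal-probability-plot envelopes.

See `docs/methods.md` for the numerical and statistical choices, including
the boundary degeneracies of this family and how fits on them are flagged.

## Worked example

```python
import oepiv as op

# --- distribution fitting ------------------------------------------------
params = op.OEPIVParams(lam=0.3, a=0.4, theta=0.5, alpha=0.2)
x = op.oepiv_rvs(500, params, seed=42)
fit = op.oepiv_fit(x)
print(fit.estimates.to_dict())   # ML estimates
print(fit.std_errors)            # delta-method standard errors
```

prints

```
{'lambda': 0.2349, 'a': 0.2498, 'theta': 0.426, 'alpha': 0.1352}
[0.0585 0.0605 0.0667 0.0311]
```

— the four parameters recovered from 500 draws (log-likelihood −1710.97,
AIC 3429.94); each estimate is within a couple of standard errors of the
generating value, the expected accuracy at this sample size.

```python
# --- censored regression -------------------------------------------------
table = op.generate_fixture("regression_sample",
                            {"n": 300, "censor_level": 0.1}, seed=1)
sample = op.to_censored_sample(table)
reg = op.fit_ml(sample)
for name, est, se, p in zip(reg.param_names, reg.theta,
                            reg.std_errors, reg.p_values):
    print(f"{name:>6}: {est: .4f}  (SE {se:.4f}, p={p:.3g})")
```

prints

```
 beta0: -1.8086  (SE 0.6341, p=0.00434)
 beta1:  1.2050  (SE 0.2598, p=3.51e-06)
 sigma:  0.3029  (SE 0.2280, p=0.184)
   lam:  0.0732  (SE 0.0571, p=0.2)
 alpha:  0.2283  (SE 0.1583, p=0.149)
```

— the covariate effect β₁ (truth 1.0) is strongly significant, while the
shape parameters are individually weakly identified at n = 300 (their Wald
p-values are large because λ, σ and α trade off against each other; see the
methods note).

The same surface is available from the shell:

```
oepiv generate --kind regression_sample --n 300 --censor-level 0.1 --seed 1 --out data.csv
oepiv regress --input data.csv --covariates x1 --out fit.json
oepiv diagnose --fit fit.json --input data.csv --covariates x1 --out diag.json
```

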