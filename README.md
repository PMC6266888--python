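# markovpot

Markov-chain peaks-over-threshold (POT) modelling of water-quality
minima, for estimating lake **nutrient and chlorophyll-a reference
conditions** — the concentration levels least impacted by human
activity — from monthly monitoring time series.

Classical extreme-value estimators (block GEV, declustered POT) assume
independent extremes, so on serially dependent monitoring data they must
discard most observations, which inflates the uncertainty of the
estimated reference value.  `markovpot` instead models the dependence:
it couples a generalized Pareto exceedance margin with a bivariate
logistic extreme-value copula on lag-1 pairs under a first-order Markov
assumption, and fits all exceedances by censored maximum likelihood.
The payoff is a reference-condition quantile with a much tighter
confidence interval from the same data.

The package is aimed at environmental statisticians and lake managers
working with multi-site monthly series of total nitrogen (TN), total
phosphorus (TP), chlorophyll a, or similar trophic-state variables.

## Model

Minima are handled by negating the series (`x -> -x`), turning the
lower tail into an upper tail.  On the negated scale, with threshold
`u`, the model has three parts:

1. **Margin.**  Exceedances follow a generalized Pareto distribution,

       H(y) = 1 − [1 + ξ(y − u)/σ]^(−1/ξ),   y > u,

   with exceedance rate λ_u = P(X > u) estimated by the sample
   fraction, giving the marginal cdf
   F(x) = 1 − λ_u[1 + ξ(x − u)/σ]^(−1/ξ) for x ≥ u, censored at
   F(u) = 1 − λ_u below.

2. **Dependence.**  Transformed to standard Fréchet, z = −1/log F(x),
   lag-1 pairs follow the logistic bivariate extreme-value law

       G(z_t, z_{t−1}) = exp{ −(z_t^(−1/α) + z_{t−1}^(−1/α))^α },

   with dependence parameter α ∈ (0, 1]: α = 1 is independence, α → 0
   complete dependence; the tail-dependence coefficient is
   χ = 2 − 2^α.

3. **Likelihood.**  Under the first-order Markov property each chain
   contributes m(x₁) · Π_t f(x_t, x_{t−1}) / m(x_{t−1}), where f is
   the four-region censored pair density (full mixed partial of G when
   both coordinates exceed u, a single partial at the censoring point
   when one does, the mass G(z_u, z_u) = (1 − λ_u)^(2^α) when neither
   does) and m is the censored marginal contribution.  Site series are
   independent chains; (σ, ξ, α) are estimated jointly by numerical
   maximum likelihood, with standard errors from the observed
   information.

The **reference condition** is the p-quantile (default p = 0.25) of the
fitted minima model back on the concentration scale,
−[u + (σ/ξ)(p^(−ξ) − 1)], with a 95% confidence interval from a
parametric (model-based) bootstrap that preserves the serial dependence.

## Worked example

```python
import markovpot as mp

ds, truth = mp.make_fixture("TN-like")          # synthetic TN series, mg/L
model = mp.MarkovPOT.from_concentrations(ds, threshold=-1.0)
res = model.fit()
print(res.summary())
q = res.bootstrap_ci(p=0.25, n_boot=500, seed=1)
print(f"reference condition (25% quantile): {q.value:.2f} mg/L")
print(f"95% bootstrap CI: ({q.ci_low:.2f}, {q.ci_high:.2f}) mg/L")
```

prints

```
Markov POT (censored logistic) fit
==============================================
variable: TN    chains: 8
threshold u (negated): -1
observations: 1152    effective (exceedances): 150
lambda_u: 0.1302    log-likelihood: -305.0742
converged: True    cov reliable: True
----------------------------------------------
param       estimate     std err
sigma         0.2619      0.0289
xi           -0.3166      0.0633
alpha         0.7935      0.0338

reference condition (25% quantile): 0.71 mg/L
95% bootstrap CI: (0.66, 0.76) mg/L
```

The fixture is an 8-site × 144-month dataset generated with
(σ, ξ, α) = (0.23, −0.27, 0.78): all 1152 observations enter the
likelihood, 150 of them as effective (above-threshold) values; α̂ ≈ 0.79
says consecutive monthly minima are strongly dependent, so an
independent-extremes analysis of the same series would be
over-optimistic about its effective sample size.  The reference
condition 0.71 mg/L is the TN level below which the fitted minima model
puts 25% probability, with its bootstrap 95% interval.

The same pipeline is scriptable from the shell:

```bash
markovpot simulate --preset TN-like --out tn.csv
markovpot fit -i tn.csv -v TN -u -1.0 --bootstrap-reps 1000 --seed 1 -o out/
markovpot diagnose -i tn.csv -v TN -u -1.0 -o out/
markovpot compare out/TN_fit.json -e GEV:0.58:0.84 -e POT:0.55:0.77
```

`fit` writes a JSON report (parameters, standard errors, quantile, CI,
seed); `diagnose` writes autocorrelation and PP/QQ/return-level arrays
as CSV (optionally a three-panel figure); `compare` tabulates pairwise
CI-length reductions, `100·(1 − len_b/len_a)`.

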