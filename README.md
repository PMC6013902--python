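# rrsim

Risk-ratio regression for common binary outcomes, and the Monte-Carlo
machinery to evaluate it under model misspecification.

When a binary outcome is common, the odds ratio from logistic regression
overstates the risk ratio (RR), so epidemiologists reach for one of two
model-based alternatives:

- **Log-binomial regression** — a binomial GLM with log link,
  log P(Y=1 | x) = x'β, fitted by constrained maximum likelihood.  Fitted
  probabilities must stay below one, so the MLE can sit on the boundary of
  the parameter space; `rrsim` fits it by iteratively reweighted least
  squares (weights p/(1−p), working response η + (y−p)/p) combined with the
  **COPY method**: the data are augmented with c−1 copies of the original
  observations plus one outcome-flipped copy (implemented as frequency
  weights (c−1)/c and 1/c), which pulls the optimum into the interior with
  an O(1/c) perturbation of the estimate (c = 10,000 by default).
- **Robust (modified) Poisson regression** — the Poisson score equations
  Σᵢ(yᵢ − μᵢ)xᵢ = 0 with μᵢ = exp(xᵢ'β) applied to the binary outcome
  (a quasi-likelihood estimate, free of the dispersion parameter), paired
  with the classical sandwich variance B⁻¹MB⁻¹, where B = Σ μᵢxᵢxᵢ' and
  M = Σ (yᵢ−μᵢ)²xᵢxᵢ', because the Poisson variance function is wrong for
  Bernoulli data.

Both estimate exp(β₁) as an adjusted risk ratio.  The package also ships a
28-scenario simulation registry that probes when the two disagree: outcome
probabilities generated through log, logit or probit links, with the linear
index optionally floored at a threshold ("truncation", putting 1.4–5.8% of
exposed subjects at the maximum outcome probability), maximum exposed
probabilities of 0.75/0.85/0.95, and a true multiplicative RR of 3 (or 2).
Replicate estimates are reduced to relative bias, empirical SE and MSE of
the log RR.  The headline finding this machinery reproduces: log-binomial
point estimates acquire a negative bias (down to roughly −12% relative bias)
as soon as the link is misspecified or a spike of large outcome
probabilities appears, while the robust Poisson estimates stay essentially
unbiased at a small cost in variance.

## Worked example

Simulate one cohort of 1000 subjects from scenario VII-1 (probit-generated
outcome probabilities, no truncation, true RR = 3) and fit both models:

```python
from rrsim import get_scenario, simulate_dataset, LogBinomial, RobustPoisson

spec = get_scenario("VII-1")
df = simulate_dataset(spec, n=1000, seed=42).to_dataframe()
print(LogBinomial.from_formula("y ~ x + z1 + z2", df).fit().summary())
print(RobustPoisson.from_formula("y ~ x + z1 + z2", df).fit().summary())
```

```
Log-binomial regression (COPY method)
  n = 1000, copies = 10000, converged = True (10 iterations)
  max fitted probability = 1.0000, log-likelihood = -153.2873
  term              coef        se        RR                95% CI
  intercept      -1.3595    0.2217    0.2568      [ 0.1663,  0.3965]
  x               1.3822    0.2210    3.9835      [ 2.5834,  6.1425]
  ...

Robust (modified) Poisson regression
  n = 1000, converged = True (8 iterations)
  max fitted mean = 1.4392  (sandwich SEs)
  term              coef   robust se        RR                95% CI
  intercept      -1.1348      0.2018    0.3215      [ 0.2165,  0.4775]
  x               1.5263      0.2438    4.6011      [ 2.8534,  7.4195]
  ...
```

On this single cohort the exposure coefficient (the log RR; truth
log 3 ≈ 1.099) differs visibly between the models, and the log-binomial fit
is pinned near the probability boundary (max fitted probability ≈ 1).  The
systematic picture needs replication:

```python
from rrsim.experiment import RunConfig, run_scenario

run = run_scenario(spec, RunConfig(replicates=1000, n=1000, base_seed=20180622))
for model, m in run.metrics.items():
    print(f"{model:15s} rel_bias={m.relative_bias_pct:+.1f}%  "
          f"emp_se={m.empirical_se:.3f}  mse={m.mse:.3f}  reps={m.reps_used}")
```

```
log-binomial    rel_bias=-6.6%  emp_se=0.202  mse=0.046  reps=1000
robust-poisson  rel_bias=+1.0%  emp_se=0.221  mse=0.049  reps=1000
```

Across 1000 replicates the log-binomial estimate of the log RR is biased
about −6% by the misspecified (probit) link alone, while the robust Poisson
estimate is unbiased with a slightly larger spread — the trade-off at the
heart of the study.  Both models are always fitted to the same datasets;
any replicate on which a fit fails to converge is excluded from both
summaries (rare: at most ~1 in 1000).

The same machinery is scriptable from a shell:

```sh
rrsim scenarios                         # list the 28-scenario registry
rrsim simulate III-4 -n 1000 --seed 1 -o cohort.csv
rrsim fit-logbin cohort.csv --formula "y ~ x + z1 + z2" --copies 10000
rrsim fit-robpois cohort.csv
rrsim run --scenarios "III-*,VII-*" --reps 1000 --out study/
```

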