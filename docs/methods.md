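# Methods

## Estimands and models

Both estimators target the adjusted risk ratio RR = P(Y=1|X=1,Z)/P(Y=1|X=0,Z)
for a binary exposure X, conditioned on covariates Z, via the exposure
coefficient of a log-link linear model log P(Y=1) = β₀ + β₁X + β₂Z₁ + β₃Z₂.
All observations are assumed independent; no clustering structures are
supported.

**Log-binomial regression** is the binomial MLE under that model.  The
log-likelihood ℓ(β) = Σ yᵢ log pᵢ + Σ (1−yᵢ) log(1−pᵢ) with pᵢ = exp(xᵢ'β)
is maximised subject to xᵢ'β < 0 for every row.  Fisher scoring for this GLM
is iteratively reweighted least squares,

    β ← (X'WX)⁻¹ X'Wz,   W = diag(pᵢ/(1−pᵢ)),   zᵢ = ηᵢ + (yᵢ−pᵢ)/pᵢ.

The weight pᵢ/(1−pᵢ) diverges as pᵢ → 1, which is both the numerical
difficulty (boundary optima) and the statistical mechanism by which
observations with large fitted probabilities dominate — and bias — the fit
under misspecification.

Because the constrained MLE can lie on the boundary, every log-binomial fit
uses the **COPY method**: the expanded data consist of the original rows
with frequency weight (c−1)/c plus an outcome-flipped duplicate block with
weight 1/c.  This is algebraically identical (up to likelihood scale) to
c−1 literal copies plus one flipped copy, but with memory independent of c.
The expanded likelihood, equivalent to a Bernoulli likelihood with
fractional response ỹ = y + (1−2y)/c, always has an interior optimum.  The
perturbation of a fitted group log-probability is ≈ (1−2p)/(c·p), so the
default c = 10,000 reproduces unconstrained interior MLEs to roughly three
decimal places, degrading where fitted probabilities are very small.
Raising c tightens this at no memory cost (the `n_copies` option).

**Robust Poisson regression** solves the Poisson quasi-score equations
Σ (yᵢ−μᵢ)xᵢ = 0 with μᵢ = exp(xᵢ'β).  The quasi-likelihood is globally
concave, there is no boundary constraint (fitted μᵢ may exceed 1), and the
dispersion parameter cancels from the equations.  Standard errors come from
the classical sandwich B⁻¹MB⁻¹ with bread B = Σ μᵢxᵢxᵢ' (observed and
expected information coincide for the log link) and meat
M = Σ (yᵢ−μᵢ)²xᵢxᵢ', evaluated at the estimate.  Raw residuals are used
with no small-sample inflation or leverage correction, so the estimator is
the plain HC0-type sandwich.

## Fitting: parameters and numerical choices

Log-binomial (`LogBinomialOptions`):

- `n_copies = 10_000` — COPY copies; estimate perturbation O(1/c).
- `tol = 1e-4` — convergence is declared when **both** the maximum absolute
  coefficient change and the relative change in the expanded weighted
  log-likelihood fall below `tol`.  A likelihood-only criterion can stop
  while coefficients still drift near a flat boundary optimum; requiring
  both is the conservative choice.
- `max_iter = 5000` — boundary-adjacent optima converge linearly and slowly
  under the dual criterion; replicates needing several hundred iterations
  occur at a per-mille rate in the truncated probit scenarios, and
  iterations are cheap (one weighted 4×4 solve).  With this cap,
  non-convergence is a genuine signal rather than an artefact of
  impatience.
- `init_intercept = -4`, `use_wls_init = True` — slopes start from an
  ordinary least-squares fit of log((y + 0.5·ȳ)/1.5) (the smoothing keeps
  the log finite at y = 0); the intercept is then forced to −4, and shifted
  further down in the rare case some row still has x'β ≥ 0.  Any interior
  start works; estimates on interior problems agree across initialisers to
  1e−3 (tested).
- Step-halving (up to 20 halvings) guards each IRLS update: a proposal is
  accepted only if every expanded-row probability stays below 1 and the
  expanded likelihood does not decrease, so accepted iterations ascend the
  likelihood by construction.

Robust Poisson: Fisher scoring from intercept log(ȳ), slopes 0, with
step-halving on the concave quasi-likelihood; `tol = 1e-10` on the
coefficient step (the problem is smooth and unconstrained, so machine-level
convergence is cheap).

Degenerate inputs: a constant response (all 0 or all 1) has a boundary MLE
at infinity for both models; the log-binomial fit flags this as `boundary`
(under COPY it otherwise converges innocently to p ≈ 1/c), and the Poisson
fit reports `converged = False`.  Non-binary responses and rank-deficient
designs raise errors.

## The data-generating process

Each simulated cohort draws, per subject: Z₁ ~ Bernoulli(0.5),
Z₂ ~ Uniform[0,1] (independent); exposure X ~ Bernoulli(expit(−1+Z₁+Z₂)),
giving mean exposure 0.5; and outcome Y ~ Bernoulli(p) with

    g(p₀) = α − max(Z₁ + b·Z₂, t)   for unexposed subjects,
    p₁ = RR · p₀                     for exposed subjects,

for link g ∈ {log, logit, probit}, Z₂ coefficient b ∈ {2, 3, 4}, truncation
floor t, and RR ∈ {2, 3}.  With t = 0 the model is perfectly linear in the
index; t > 0 floors the index, creating a spike of subjects at the maximum
outcome probability — by design 1.4, 2.8 or 5.8% of exposed subjects
(thresholds scale with b because Z₂ is uniform).  The intercepts α are
fixed registry constants, chosen so the maximum exposed probability is
0.75, 0.85 or 0.95; they are stored to the two decimal places of the design
(so realised maxima differ from the nominal ones by under a cent), and
`derive_intercept` provides the analytic consistency check
α = g(max_p/RR) + t.  The stored VII-4 intercept (−0.12) disagrees in sign
with the derivation (+0.12); it is kept verbatim as a documented
inconsistency rather than silently corrected.

One random stream per dataset, draw order covariates → exposure → outcome,
so (scenario, n, seed) fully determines a cohort.  At a truncation tie
(index exactly equal to t) the floor applies, via max().

What the generator does **not** emulate: real covariate structure
(correlated or continuous confounders beyond one uniform variable),
measurement error, missingness, clustering, or effect modification.  A
passing study therefore demonstrates the estimators' behaviour under link
misspecification and index truncation specifically — not robustness to
every misspecification met in applied data (omitted variables and ignored
interactions, for instance, are out of scope here).

## The Monte-Carlo study

Per scenario, `replicates = 1000` cohorts of `n = 1000` (alternative 500)
are simulated; each cohort is fitted by **both** models; a replicate on
which either fit fails to converge is excluded from both models' summaries,
so every comparison uses identical datasets (paired exclusion).  Replicate
m is seeded from (base seed, CRC-32 of the scenario id, m) through a
`SeedSequence`, making results independent of execution order and
parallelism.  Estimates of the exposure coefficient reduce to

    relative bias (%) = 100 · mean((θ̂ − log RR)/log RR)
    empirical SE      = sample SD of θ̂   (n−1 denominator)
    MSE               = (mean θ̂ − log RR)² + sample variance,

so MSE = bias² + variance holds as an identity.  The n−1 denominator is a
choice the design leaves open; at 1000 replicates it is numerically
irrelevant (<0.1%).

Problem sizes used by the shipped checks: the full-scale acceptance tests
run 15 scenarios at 1000 replicates of n = 1000 (about a minute); the
design-calibration quantities use 10⁶ subjects; the remaining unit and
property tests use cohorts of a few hundred subjects.

## Known limitations

- The COPY device yields an approximate, not exact, constrained MLE; its
  O(1/(c·p)) perturbation grows as fitted probabilities shrink.  Exact
  boundary-constrained optimisation and exact small-sample methods are out
  of scope.
- The sandwich variance is the uncorrected classical form; in very small
  samples it is known to understate the true standard errors.
- Only log, logit and probit generating links are covered; complementary
  log-log and log-log links, GEE working-correlation structures, and
  coverage-probability metrics are not implemented.
- The minimal formula interface parses additive terms only (`y ~ x + z1 + z2`);
  interactions and transformations require building the design matrix
  directly.
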