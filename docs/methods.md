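# Methods

## Model

Each arm `d ∈ {c, t}` of the two-arm phase II trial is modeled
independently:

```
Y_d ~ Binomial(n_d, pi_d),   pi_d = expit(theta_d),
theta_d ~ Normal(mu_d, sigma_d^2).
```

The independent-arm structure is deliberate: no information is borrowed
between arms, the joint posterior factorizes into two one-dimensional
posteriors, and the comparison of arms is driven entirely by the data.
Defaults `mu_d = 0`, `sigma_d = 2` put ~95% prior mass on response rates
between roughly 2% and 98% — diffuse enough that with 250 patients per arm
the likelihood dominates. If phase I information exists, the prior
hyperparameters can encode it.

The futility rule declares the treatment futile when

```
P(pi_t - pi_c < Delta | Y_t, Y_c, n_t, n_c) > gamma
```

with `Delta = 0.09` and `gamma = 0.90` by default. The comparison is
**strict**: a probability of exactly 0.90 does not declare futility.

## Posterior computation

**MCMC (default).** Because the arms share no parameters, the
Metropolis-within-Gibbs structure reduces to two independent random-walk
Metropolis chains on `theta_d`. Defaults: 2500 total iterations, the first
1000 discarded as burn-in, no thinning (1500 retained draws per arm).
Tuning choices, since only chain lengths are externally specified:

- *Proposal*: Gaussian random walk, initial SD 0.5. During burn-in only,
  the SD is rescaled every 100 iterations (×0.7 if the window acceptance
  rate is below 20%, ×1.4 if above 50%), so the retained chain comes from
  a fixed kernel. With n = 250 per arm the realized acceptance rates land
  near 35–45%.
- *Initialization*: the empirical logit `log((Y+0.5)/(n−Y+0.5))`; the +0.5
  keeps the start finite at Y ∈ {0, n} and the chain starts essentially at
  the posterior mode, so burn-in is generous.
- *Numerics*: `log(1+e^theta)` is computed via a stable softplus, so the
  log posterior is finite for any finite `theta`.
- *Seeding*: each run takes one root seed; the two arm chains use
  independent `SeedSequence` children, making runs bit-reproducible.

**Quadrature oracle.** The same one-dimensional posterior is also
evaluated deterministically: a uniform grid of ≥ 100 points (2001 by
default) on the log-odds scale spanning ±8 approximate posterior SDs
around a precision-weighted combination of the empirical logit and the
prior mean; log densities normalized by log-sum-exp; trapezoid masses
renormalized to sum to 1. The grid lives in `theta`, not `pi`, to avoid
the Jacobian singularities at the boundaries. Under the product of the two
grid measures, `P(pi_t − pi_c < Delta)` is an exact double sum (computed
with cumulative control-arm tail masses, O(G log G)). The quadrature path
is both an independent cross-check of the sampler in the test suite and a
fast evaluation mode for simulations; MCMC remains the reference mode.

## Predictive probability of phase III success

For a future trial with `n` patients per arm and one-sided level `alpha`,
the power at fixed rates is the unpooled-variance normal approximation
without continuity correction:

```
power(pi_t, pi_c) = Phi( (pi_t − pi_c)·sqrt(n) / sqrt(pi_t q_t + pi_c q_c) − z_{1−alpha} )
```

This is the standard "plug in the estimated rate of each arm" form; at
`pi_t = pi_c` it returns exactly `alpha`, and draws with `pi_t < pi_c`
contribute near-zero power rather than being truncated, so the average
over the posterior is faithful. The predictive probability of success is
the mean of `power` over joint posterior draws (MCMC) or the exact double
sum over the product grid (quadrature).

Two summaries are reported at the study level: the unconditional mean over
all simulated trials (the default headline number) and the mean restricted
to trials *not* declared futile. The conditional variant answers "given we
proceed, how likely is phase III to succeed" and is emitted alongside
because either conditioning can be of interest when reading the summary
table.

The companion sample-size calculator inverts the same formula:
`n ≥ (z_{1−alpha} + z_{power})² (pi_c q_c + pi_t q_t) / diff²`, ceiled per
arm. With the default future trial (80% power, 2.5% one-sided alpha,
difference 0.09) it returns 441 per arm — 882 total — at a baseline
control rate of 0.312. The package treats the baseline as a configuration
input; 0.312 is the rate at which the default future-trial size of 882 is
recovered exactly.

## Simulation study

Operating characteristics are estimated by simulating trials under fixed
true rates: `Y_c ~ Binomial(250, pi_c_true)` and
`Y_t ~ Binomial(250, pi_c_true + effect)` independently, evaluating each
trial with the futility rule, and aggregating. Defaults: 1000 simulations
per scenario, true effects 0 (characterizing power — correctly declaring a
non-superior treatment futile) and 0.09 (characterizing type I error —
wrongly declaring futile a treatment that truly meets the margin). The
true control rate defaults to **0.30**, chosen once because
normal-approximation calculations at baselines near 0.30–0.31 are
consistent with both the design's published operating characteristics and
a future-trial size near 882; it is exposed in the configuration.

Monte Carlo bookkeeping: the proportion futile carries the binomial SE
`sqrt(p(1−p)/N)` (≈ 0.0125 at p ≈ 0.8, ≈ 0.009 at p ≈ 0.09 with N =
1000); the mean predictive probability carries the sample-SD-based SE.
Per-simulation sub-seeds are `SeedSequence(root_seed,
spawn_key=(scenario_index, sim_index))` children, so every simulated trial
is reproducible in isolation and results are independent of execution
order.

What the generator emulates — and does not: it reproduces exactly the
idealized conditions under which such designs are characterized
(independent binomial arms at known true rates, no dropout, no interim
looks, perfectly observed binary outcomes). Passing tests therefore
certify the decision machinery and its frequentist properties under the
stated model, not robustness to missing data, drift in the control rate,
or misclassified outcomes.

## Problem sizes in the test suite

Unit and property tests run scaled-down chains or the quadrature path with
a 501-point grid; the end-to-end checks re-estimate the operating
characteristics from 1000 simulated trials per scenario in quadrature
mode, and `scripts/acceptance.py` runs the full MCMC study (1000
simulations per scenario, 2500-iteration chains). Monte Carlo comparisons
between sampler and oracle use batch-means standard errors (30 batches) to
account for chain autocorrelation, with a 3-SE acceptance band.

## Known limitations

- No interim analyses: the rule is applied once, at the final analysis.
  Group-sequential extensions would need an explicit stopping boundary.
- No convergence diagnostics beyond acceptance-rate logging; the 1-D
  posteriors here are unimodal and well behaved, but the sampler is not a
  general-purpose MCMC engine.
- The future-trial power is a closed-form normal approximation; designs
  whose phase III analysis differs materially (exact tests, covariate
  adjustment, non-inferiority margins) need their own power function.
- Equal allocation is assumed for the future trial; the phase II design
  accepts any two-arm allocation.
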