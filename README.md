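# futilitysim

Design and simulation engine for **Bayesian two-arm phase II futility
trials** with a binary endpoint.

A futility (non-superiority) trial flips the usual phase II logic: the null
hypothesis is that the new treatment meets or exceeds a margin of
superiority over control,

```
H0: pi_t - pi_c >= Delta        H1: pi_t - pi_c < Delta
```

where `pi_c`, `pi_t` are the probabilities of a favorable outcome in the
control and treatment arms and `Delta` is the minimal difference worth a
confirmatory study. Rejecting H0 declares the treatment *futile* — not
worth taking to phase III. The audience is trial statisticians who want an
open, scriptable alternative to commercial trial-simulation software for
this class of designs.

## Model and decision rule

Each arm is modeled independently (the "independent dose model"):

```
Y_d ~ Binomial(n_d, pi_d),   pi_d = e^{theta_d} / (1 + e^{theta_d}),
theta_d ~ Normal(mu_d, sigma_d^2),       d in {c, t},
```

with diffuse defaults `mu_d = 0`, `sigma_d = 2` on the log-odds scale. At
the final analysis the trial declares futility when the posterior
probability

```
P(pi_t - pi_c < Delta | Y_t, Y_c, n_t, n_c)  >  0.90     (strict)
```

The posterior is sampled by Metropolis-within-Gibbs (the two arms share no
parameters, so the Gibbs structure is two independent random-walk
Metropolis chains on the log-odds), or evaluated deterministically on a
quadrature grid — the two agree to Monte Carlo error and the grid version
serves as the exact oracle in the test suite.

Alongside the decision, the package computes the **posterior-predictive
probability of phase III success**: the one-sided normal-approximation
power of a specified future trial (default 882 patients, 2.5% one-sided
alpha), averaged over the joint posterior of `(pi_t, pi_c)`. A
sample-size calculator for that future trial is included
(`required_sample_size`), and an operating-characteristics simulator
estimates the design's power and type I error by simulating many trials
under fixed true response rates.

## Worked example

Evaluate a completed trial with 75/250 control and 98/250 treatment
responders:

```console
$ futilitysim evaluate --yc 75 --nc 250 --yt 98 --nt 250 --mode quadrature
P(futility) = P(pi_t - pi_c < 0.09 | data) = 0.484073
Declare futility (> 0.9): NO
Predictive probability of phase III success (n=882): 0.709362
```

The observed difference (0.392 − 0.300 = 0.092) slightly exceeds the 0.09
margin, so only 48% of the posterior mass lies below the margin — far
short of the 0.90 needed to declare futility — and a future 882-patient
phase III trial would succeed with predictive probability about 0.71.

Size that future trial from a 31.2% control rate:

```console
$ futilitysim power --pi-c 0.312
required sample size: 441 per arm, 882 total
```

Run a full operating-characteristics study from a YAML config
(`futilitysim simulate --config run.yaml`); it writes per-trial records
(`trials.csv`), per-scenario summaries (`summary.csv`/`.json`) and a
`manifest.json` echoing the configuration. The same machinery is available
as a library:

```python
import futilitysim as fs

ocs = fs.run_simulation_study(
    [fs.Scenario(true_pi_control=0.30, true_effect=0.0, n_simulations=1000)],
    fs.TrialDesign(), fs.FutureTrialSpec(), fs.McmcSettings(seed=0),
    root_seed=1,
)
print(fs.summarize(ocs, fs.TrialDesign()))
```

## Documentation

See `docs/methods.md` for the model, sampler tuning, quadrature oracle,
the assumptions behind the predictive-probability calculation, and known
limitations.
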