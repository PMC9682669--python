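"""Bayesian two-arm phase II futility trial design.

A phase II futility (non-superiority) trial tests the null hypothesis that a
new treatment meets or exceeds a margin of superiority over control,

    H0: pi_t - pi_c >= Delta      vs.      H1: pi_t - pi_c < Delta,

where ``pi_c`` and ``pi_t`` are the probabilities of a favorable outcome in
the control and treatment arms.  Rejecting H0 declares the treatment futile:
not worth a confirmatory phase III trial.

Each arm is modeled independently ("independent dose model"):

    Y_d ~ Binomial(n_d, pi_d),    pi_d = expit(theta_d),
    theta_d ~ Normal(mu_d, sigma_d^2),        d in {c, t},

with diffuse defaults mu_d = 0, sigma_d = 2 on the log-odds scale.  The trial
decision rule declares futility when the posterior probability

    P(pi_t - pi_c < Delta | Y_t, Y_c, n_t, n_c)

strictly exceeds a threshold (0.90 by default).  Alongside the decision, the
posterior-predictive probability of success of a hypothetical future phase III
trial is computed by averaging the frequentist power of that trial over the
joint posterior of (pi_t, pi_c).

The module is organised in the order the method runs:

1.  configuration defaults and logging;
2.  domain types (priors, counts, design, MCMC settings, posterior draws);
3.  the core model: likelihood, Metropolis-within-Gibbs sampler, and a
    deterministic quadrature evaluator of the same posterior;
4.  the futility probability and single-trial decision;
5.  the future-trial power / sample-size calculator and the predictive
    probability of phase III success;
6.  the operating-characteristics simulation study;
7.  configuration files and report writing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logsumexp
from scipy.stats import norm

__all__ = [
    "PriorSpec",
    "ArmCount",
    "TrialDesign",
    "McmcSettings",
    "PosteriorDraws",
    "QuadraturePosterior",
    "TrialDecision",
    "FutureTrialSpec",
    "Scenario",
    "OperatingCharacteristics",
    "RunConfig",
    "inverse_logit",
    "log_posterior_theta",
    "sample_posterior",
    "quadrature_posterior",
    "quadrature_joint",
    "posterior_prob_futility",
    "evaluate_trial",
    "two_proportion_power",
    "required_sample_size",
    "predictive_prob_success",
    "simulate_trial_data",
    "run_simulation_study",
    "summarize",
    "load_config",
    "save_config",
    "draws_to_frame",
    "write_study_outputs",
]

# --------------------------------------------------------------------------
# Configuration defaults and logging
# --------------------------------------------------------------------------

logger = logging.getLogger("futilitysim")

#: Default margin of superiority (Delta) on the risk-difference scale.
DEFAULT_DELTA = 0.09
#: Default posterior-probability threshold for declaring futility (strict >).
DEFAULT_FUTILITY_THRESHOLD = 0.90
#: Default total phase II sample size, split equally between arms.
DEFAULT_N_TOTAL = 500
#: Default prior on the per-arm log-odds: Normal(0, 2^2).
DEFAULT_PRIOR_MU = 0.0
DEFAULT_PRIOR_SIGMA = 2.0
#: Default quadrature resolution (points on the theta grid).
DEFAULT_N_GRID = 2001
#: Target window for the random-walk acceptance rate during burn-in adaptation.
_ADAPT_TARGET = (0.20, 0.50)
_ADAPT_WINDOW = 100


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior on an arm's log-odds of favorable outcome.

    Parameters
    ----------
    mu : float
        Prior mean of theta_d (log-odds scale).  Default 0.
    sigma : float
        Prior standard deviation of theta_d.  Must be > 0.  Default 2,
        a diffuse choice: it places ~95% prior mass on response rates
        between roughly 2% and 98%.
    """

    mu: float = DEFAULT_PRIOR_MU
    sigma: float = DEFAULT_PRIOR_SIGMA

    def __post_init__(self) -> None:
        _require(math.isfinite(self.mu), "prior mu must be finite")
        _require(self.sigma > 0 and math.isfinite(self.sigma), "prior sigma must be > 0")


@dataclass(frozen=True)
class ArmCount:
    """Observed (or simulated) favorable outcomes for one arm.

    ``successes`` is Y_d, ``n`` is the number of subjects randomized to the
    arm, and ``arm_label`` is "control" or "treatment".
    """

    successes: int
    n: int
    arm_label: str = "control"

    def __post_init__(self) -> None:
        _require(int(self.n) == self.n and self.n > 0, "n must be a positive integer")
        _require(
            int(self.successes) == self.successes and 0 <= self.successes <= self.n,
            "successes must be an integer in [0, n]",
        )
        _require(self.arm_label in ("control", "treatment"), "arm_label must be 'control' or 'treatment'")


@dataclass(frozen=True)
class TrialDesign:
    """Fixed design parameters of the phase II futility trial."""

    n_total: int = DEFAULT_N_TOTAL
    allocation: tuple[int, int] | None = None  # (control, treatment); equal if None
    delta: float = DEFAULT_DELTA
    futility_threshold: float = DEFAULT_FUTILITY_THRESHOLD
    prior_control: PriorSpec = field(default_factory=PriorSpec)
    prior_treatment: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        _require(int(self.n_total) == self.n_total and self.n_total > 0, "n_total must be a positive integer")
        if self.allocation is None:
            _require(self.n_total % 2 == 0, "equal allocation requires an even n_total")
            object.__setattr__(self, "allocation", (self.n_total // 2, self.n_total // 2))
        alloc = tuple(int(a) for a in self.allocation)
        _require(len(alloc) == 2 and all(a > 0 for a in alloc), "allocation must be two positive integers")
        _require(sum(alloc) == self.n_total, "allocation must sum to n_total")
        object.__setattr__(self, "allocation", alloc)
        _require(0.0 < self.delta < 1.0, "delta must lie strictly in (0, 1)")
        _require(0.0 < self.futility_threshold < 1.0, "futility_threshold must lie strictly in (0, 1)")

    @property
    def n_control(self) -> int:
        return self.allocation[0]

    @property
    def n_treatment(self) -> int:
        return self.allocation[1]


@dataclass(frozen=True)
class McmcSettings:
    """Metropolis-within-Gibbs sampler settings.

    Defaults follow the reference design: 1000 burn-in iterations out of
    2500 total, no thinning, leaving 1500 retained draws per arm.  The
    Gaussian random-walk proposal standard deviation starts at
    ``proposal_sd`` and, when ``adapt=True``, is rescaled during burn-in to
    keep the acceptance rate between 20% and 50%.
    """

    n_burnin: int = 1000
    n_total_samples: int = 2500
    thinning: int = 1
    proposal_sd: float = 0.5
    seed: int = 0
    adapt: bool = True

    def __post_init__(self) -> None:
        _require(self.n_burnin > 0, "n_burnin must be positive")
        _require(self.n_total_samples > self.n_burnin, "n_total_samples must exceed n_burnin")
        _require(self.thinning >= 1, "thinning must be >= 1")
        _require(self.proposal_sd > 0, "proposal_sd must be > 0")
        _require(self.n_retained >= 1, "settings leave no retained draws")

    @property
    def n_retained(self) -> int:
        return (self.n_total_samples - self.n_burnin) // self.thinning


@dataclass(frozen=True)
class PosteriorDraws:
    """Joint posterior representation for (theta_c, theta_t).

    For ``source="mcmc"`` the four arrays are aligned retained draws and the
    joint distribution is their empirical measure.  For
    ``source="quadrature"`` the arrays are the per-arm grids, and
    ``weights_control`` / ``weights_treatment`` carry the normalized grid
    masses; the joint distribution is the product measure (the two arms
    share no parameters, so their posteriors are independent).
    """

    theta_control: np.ndarray
    theta_treatment: np.ndarray
    pi_control: np.ndarray
    pi_treatment: np.ndarray
    source: str = "mcmc"
    weights_control: np.ndarray | None = None
    weights_treatment: np.ndarray | None = None
    acceptance_rates: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        _require(self.source in ("mcmc", "quadrature"), "source must be 'mcmc' or 'quadrature'")
        for name in ("theta_control", "theta_treatment", "pi_control", "pi_treatment"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        _require(self.pi_control.size >= 1 and self.pi_treatment.size >= 1, "draws must be non-empty")
        if self.source == "mcmc":
            lens = {self.theta_control.size, self.theta_treatment.size, self.pi_control.size, self.pi_treatment.size}
            _require(len(lens) == 1, "mcmc draws must have equal length across arrays")
        else:
            _require(
                self.weights_control is not None and self.weights_treatment is not None,
                "quadrature draws require per-arm weights",
            )
        for pi in (self.pi_control, self.pi_treatment):
            _require(bool(np.all((pi > 0.0) & (pi < 1.0))), "pi draws must lie strictly in (0, 1)")

    @property
    def n_draws(self) -> int:
        return int(self.pi_control.size)


@dataclass(frozen=True)
class QuadraturePosterior:
    """Deterministic grid approximation to one arm's posterior.

    ``theta`` is an ascending grid on the log-odds scale, ``pi`` its
    inverse-logit image, and ``weights`` the trapezoid-rule masses of the
    normalized posterior density, summing to 1.
    """

    theta: np.ndarray
    pi: np.ndarray
    weights: np.ndarray

    @property
    def mean_pi(self) -> float:
        return float(np.dot(self.weights, self.pi))

    @property
    def mean_theta(self) -> float:
        return float(np.dot(self.weights, self.theta))


@dataclass(frozen=True)
class TrialDecision:
    """Outcome of evaluating one completed trial against the futility rule."""

    y_control: int
    n_control: int
    y_treatment: int
    n_treatment: int
    p_futility: float
    declared_futile: bool
    pred_prob_success: float | None = None
    mode: str = "mcmc"


@dataclass(frozen=True)
class FutureTrialSpec:
    """The hypothetical phase III trial whose success is predicted.

    Defaults: 882 patients total with equal allocation, sized to detect a
    0.09 difference with 80% power at one-sided alpha 0.025.
    """

    n_total_future: int = 882
    alpha_one_sided: float = 0.025
    target_power: float = 0.80
    detectable_difference: float = 0.09

    def __post_init__(self) -> None:
        _require(self.n_total_future > 0 and self.n_total_future % 2 == 0, "n_total_future must be a positive even integer")
        _require(0.0 < self.alpha_one_sided < 0.5, "alpha_one_sided must lie in (0, 0.5)")
        _require(0.0 < self.target_power < 1.0, "target_power must lie in (0, 1)")
        _require(0.0 < self.detectable_difference < 1.0, "detectable_difference must lie in (0, 1)")

    @property
    def n_per_arm(self) -> int:
        return self.n_total_future // 2


@dataclass(frozen=True)
class Scenario:
    """A true state of nature for the simulation study."""

    true_pi_control: float
    true_effect: float
    n_simulations: int = 1000
    label: str = ""

    def __post_init__(self) -> None:
        _require(0.0 < self.true_pi_control < 1.0, "true_pi_control must lie strictly in (0, 1)")
        _require(0.0 < self.true_pi_control + self.true_effect < 1.0, "true_pi_control + true_effect must lie strictly in (0, 1)")
        _require(self.n_simulations >= 1, "n_simulations must be >= 1")
        if not self.label:
            object.__setattr__(self, "label", f"pic={self.true_pi_control:g},effect={self.true_effect:g}")

    @property
    def true_pi_treatment(self) -> float:
        return self.true_pi_control + self.true_effect


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated simulation results for one scenario."""

    scenario: Scenario
    prop_futile: float
    prop_futile_mc_se: float
    mean_predictive_prob: float
    mean_predictive_prob_conditional_not_futile: float
    mc_se_predictive: float
    n_simulations_run: int
    trials: pd.DataFrame | None = field(default=None, compare=False, repr=False)


# --------------------------------------------------------------------------
# Core model: likelihood, sampler, quadrature
# --------------------------------------------------------------------------


def inverse_logit(theta: float) -> float:
    """Inverse-logit (logistic) link: pi = exp(theta) / (1 + exp(theta)).

    Computed stably for large |theta| via :func:`scipy.special.expit`.
    Raises ``ValueError`` on non-finite input.
    """
    arr = np.asarray(theta, dtype=float)
    _require(bool(np.all(np.isfinite(arr))), "theta must be finite")
    out = expit(arr)
    return float(out) if np.ndim(theta) == 0 else out


def _softplus(t: float) -> float:
    # log(1 + exp(t)) without overflow
    return t + math.log1p(math.exp(-t)) if t > 0 else math.log1p(math.exp(t))


def log_posterior_theta(theta: float, arm: ArmCount, prior: PriorSpec) -> float:
    """Log unnormalized posterior density of one arm's log-odds theta_d.

    With Y ~ Binomial(n, expit(theta)) and theta ~ Normal(mu, sigma^2),

        log p(theta | Y) = Y*theta - n*log(1 + exp(theta))
                           + log Normal(theta; mu, sigma^2)   + const,

    where only the binomial coefficient (constant in theta) is dropped.
    Finite for all finite theta.
    """
    _require(math.isfinite(theta), "theta must be finite")
    z = (theta - prior.mu) / prior.sigma
    log_prior = -0.5 * z * z - math.log(prior.sigma) - 0.5 * math.log(2.0 * math.pi)
    return arm.successes * theta - arm.n * _softplus(theta) + log_prior


def _empirical_logit(y: int, n: int) -> float:
    # +0.5 continuity correction keeps the starting value finite at Y in {0, n}
    return math.log((y + 0.5) / (n - y + 0.5))


def _mh_chain(arm: ArmCount, prior: PriorSpec, settings: McmcSettings, seed_seq: np.random.SeedSequence) -> tuple[np.ndarray, float]:
    """Random-walk Metropolis chain targeting one arm's theta posterior.

    Returns the retained post-burn-in (thinned) theta draws and the
    post-burn-in acceptance rate.  The proposal scale is adapted only
    during burn-in (multiplicative rescaling every 100 iterations toward a
    20-50% acceptance rate), so the retained chain is a genuine
    fixed-kernel Metropolis sample.
    """
    rng = np.random.default_rng(seed_seq)
    total = settings.n_total_samples
    steps = rng.standard_normal(total)
    log_u = np.log(rng.random(total))

    y, n = arm.successes, arm.n
    mu, sigma = prior.mu, prior.sigma
    half_prec = 0.5 / (sigma * sigma)

    def lp(t: float) -> float:
        return y * t - n * _softplus(t) - (t - mu) * (t - mu) * half_prec

    theta = _empirical_logit(y, n)
    cur_lp = lp(theta)
    sd = settings.proposal_sd
    burn = settings.n_burnin
    retained = np.empty(settings.n_retained)
    k = 0
    window_acc = 0
    post_acc = 0
    for i in range(total):
        prop = theta + sd * steps[i]
        prop_lp = lp(prop)
        if log_u[i] < prop_lp - cur_lp:
            theta = prop
            cur_lp = prop_lp
            window_acc += 1
            if i >= burn:
                post_acc += 1
        if i < burn:
            if settings.adapt and (i + 1) % _ADAPT_WINDOW == 0:
                rate = window_acc / _ADAPT_WINDOW
                if rate < _ADAPT_TARGET[0]:
                    sd *= 0.7
                elif rate > _ADAPT_TARGET[1]:
                    sd *= 1.4
                window_acc = 0
        else:
            j = i - burn
            if j % settings.thinning == 0 and k < retained.size:
                retained[k] = theta
                k += 1
    acc_rate = post_acc / (total - burn)
    return retained[:k], acc_rate


def sample_posterior(
    arms: tuple[ArmCount, ArmCount],
    design: TrialDesign,
    settings: McmcSettings,
) -> PosteriorDraws:
    """Draw from the joint posterior of (theta_c, theta_t) by MCMC.

    The two arms share no parameters, so the Gibbs structure reduces to two
    independent one-dimensional Metropolis chains; each is seeded from an
    independent child of ``settings.seed``, making runs bit-reproducible.

    Parameters
    ----------
    arms : (ArmCount, ArmCount)
        Control and treatment counts, in either order (resolved by label).
    design : TrialDesign
        Supplies the per-arm priors.
    settings : McmcSettings
        Chain lengths, proposal scale, seed.
    """
    control, treatment = _resolve_arms(arms)
    ss = np.random.SeedSequence(settings.seed)
    ss_c, ss_t = ss.spawn(2)
    theta_c, acc_c = _mh_chain(control, design.prior_control, settings, ss_c)
    theta_t, acc_t = _mh_chain(treatment, design.prior_treatment, settings, ss_t)
    logger.debug("MH acceptance rates: control %.3f, treatment %.3f", acc_c, acc_t)
    return PosteriorDraws(
        theta_control=theta_c,
        theta_treatment=theta_t,
        pi_control=expit(theta_c),
        pi_treatment=expit(theta_t),
        source="mcmc",
        acceptance_rates={"control": acc_c, "treatment": acc_t},
    )


def _resolve_arms(arms: tuple[ArmCount, ArmCount]) -> tuple[ArmCount, ArmCount]:
    _require(len(arms) == 2, "exactly two arms required")
    labels = {a.arm_label for a in arms}
    _require(labels == {"control", "treatment"}, "arms must be one control and one treatment")
    control = next(a for a in arms if a.arm_label == "control")
    treatment = next(a for a in arms if a.arm_label == "treatment")
    return control, treatment


def quadrature_posterior(arm: ArmCount, prior: PriorSpec, n_grid: int = DEFAULT_N_GRID) -> QuadraturePosterior:
    """Deterministic grid approximation of one arm's posterior.

    The grid lives on the theta (log-odds) scale — not on pi, where the
    Jacobian blows up at the boundaries — and spans +/- 8 approximate
    posterior standard deviations around a precision-weighted combination
    of the empirical logit and the prior mean.  Unnormalized log densities
    are normalized by log-sum-exp and converted to trapezoid masses.
    """
    _require(n_grid >= 100, "n_grid must be >= 100")
    # Normal approximation to locate the grid: likelihood information at the
    # empirical logit is n*pihat*(1-pihat); combine with the prior precision.
    pihat = (arm.successes + 0.5) / (arm.n + 1.0)
    info_lik = arm.n * pihat * (1.0 - pihat)
    prec = info_lik + 1.0 / prior.sigma**2
    center = (_empirical_logit(arm.successes, arm.n) * info_lik + prior.mu / prior.sigma**2) / prec
    half_width = 8.0 / math.sqrt(prec)
    theta = np.linspace(center - half_width, center + half_width, n_grid)

    log_dens = arm.successes * theta - arm.n * np.logaddexp(0.0, theta) - 0.5 * ((theta - prior.mu) / prior.sigma) ** 2
    log_dens -= logsumexp(log_dens)
    dens = np.exp(log_dens)
    # trapezoid masses on the uniform grid
    w = np.full(n_grid, 1.0)
    w[0] = w[-1] = 0.5
    weights = dens * w
    weights /= weights.sum()
    return QuadraturePosterior(theta=theta, pi=expit(theta), weights=weights)


def quadrature_joint(
    arms: tuple[ArmCount, ArmCount],
    design: TrialDesign,
    n_grid: int = DEFAULT_N_GRID,
) -> PosteriorDraws:
    """Product-measure joint posterior from per-arm quadrature grids."""
    control, treatment = _resolve_arms(arms)
    qc = quadrature_posterior(control, design.prior_control, n_grid)
    qt = quadrature_posterior(treatment, design.prior_treatment, n_grid)
    return PosteriorDraws(
        theta_control=qc.theta,
        theta_treatment=qt.theta,
        pi_control=qc.pi,
        pi_treatment=qt.pi,
        source="quadrature",
        weights_control=qc.weights,
        weights_treatment=qt.weights,
    )


# --------------------------------------------------------------------------
# Futility probability and single-trial decision
# --------------------------------------------------------------------------


def posterior_prob_futility(draws: PosteriorDraws, delta: float) -> float:
    """Posterior probability of futility, P(pi_t - pi_c < delta | data).

    For MCMC draws this is the fraction of aligned joint draws satisfying
    the inequality.  For quadrature draws it is the exact double sum under
    the product of the two grid measures, computed by accumulating control
    tail masses against each treatment grid point.
    """
    _require(draws.n_draws >= 1, "draws must be non-empty")
    if draws.source == "mcmc":
        return float(np.mean(draws.pi_treatment - draws.pi_control < delta))
    # P = sum_j w_t[j] * P(pi_c > pi_t[j] - delta); pi grids ascend with theta.
    cum = np.concatenate(([0.0], np.cumsum(draws.weights_control)))
    total = cum[-1]
    idx = np.searchsorted(draws.pi_control, draws.pi_treatment - delta, side="right")
    p = float(np.dot(draws.weights_treatment, total - cum[idx]))
    return min(max(p, 0.0), 1.0)


def evaluate_trial(
    arms: tuple[ArmCount, ArmCount],
    design: TrialDesign,
    settings: McmcSettings | None = None,
    *,
    mode: str = "mcmc",
    future: FutureTrialSpec | None = None,
    n_grid: int = DEFAULT_N_GRID,
) -> TrialDecision:
    """Apply the futility decision rule to one completed trial.

    Futility is declared iff the posterior probability strictly exceeds
    ``design.futility_threshold``.  With ``future`` supplied, the
    posterior-predictive probability of phase III success is reported too.

    ``mode="mcmc"`` (the reference analysis) requires ``settings``;
    ``mode="quadrature"`` evaluates the same posterior deterministically.
    """
    _require(mode in ("mcmc", "quadrature"), "mode must be 'mcmc' or 'quadrature'")
    if mode == "mcmc":
        _require(settings is not None, "mcmc mode requires McmcSettings")
        draws = sample_posterior(arms, design, settings)
    else:
        draws = quadrature_joint(arms, design, n_grid)
    p_fut = posterior_prob_futility(draws, design.delta)
    pred = predictive_prob_success(draws, future) if future is not None else None
    control, treatment = _resolve_arms(arms)
    return TrialDecision(
        y_control=control.successes,
        n_control=control.n,
        y_treatment=treatment.successes,
        n_treatment=treatment.n,
        p_futility=p_fut,
        declared_futile=p_fut > design.futility_threshold,
        pred_prob_success=pred,
        mode=mode,
    )


# --------------------------------------------------------------------------
# Future phase III trial: power, sample size, predictive probability
# --------------------------------------------------------------------------


def two_proportion_power(pi_t, pi_c, n_per_arm: int, alpha_one_sided: float):
    """One-sided power of a two-sample test of proportions (pi_t > pi_c).

    Unpooled-variance normal approximation, no continuity correction:

        power = Phi( (pi_t - pi_c) * sqrt(n) / sqrt(pi_t q_t + pi_c q_c)
                      - z_{1-alpha} ),

    with n the per-arm sample size.  At pi_t = pi_c this returns exactly
    alpha; draws with pi_t < pi_c yield power near zero (harm is not
    truncated).  Accepts scalars or arrays (broadcast).
    """
    pt = np.asarray(pi_t, dtype=float)
    pc = np.asarray(pi_c, dtype=float)
    _require(bool(np.all((pt > 0) & (pt < 1) & (pc > 0) & (pc < 1))), "pi values must lie strictly in (0, 1)")
    _require(n_per_arm >= 1, "n_per_arm must be a positive integer")
    _require(0.0 < alpha_one_sided < 0.5, "alpha_one_sided must lie in (0, 0.5)")
    z_alpha = norm.ppf(1.0 - alpha_one_sided)
    se = np.sqrt(pt * (1.0 - pt) + pc * (1.0 - pc))
    z = (pt - pc) * math.sqrt(n_per_arm) / se - z_alpha
    out = norm.cdf(z)
    return float(out) if np.ndim(pi_t) == 0 and np.ndim(pi_c) == 0 else out


def required_sample_size(
    pi_c: float,
    difference: float,
    target_power: float = 0.80,
    alpha_one_sided: float = 0.025,
) -> int:
    """Per-arm sample size for the future trial (normal approximation).

        n >= (z_{1-alpha} + z_{power})^2 * (pi_c q_c + pi_t q_t) / difference^2

    with pi_t = pi_c + difference, ceiled to an integer.  With the package
    defaults this yields 441 per arm (882 total) at a baseline rate of
    0.312.
    """
    _require(0.0 < pi_c < 1.0 and 0.0 < pi_c + difference < 1.0, "pi_c and pi_c + difference must lie strictly in (0, 1)")
    _require(difference > 0, "difference must be positive")
    _require(0.0 < target_power < 1.0, "target_power must lie in (0, 1)")
    _require(0.0 < alpha_one_sided < 0.5, "alpha_one_sided must lie in (0, 0.5)")
    pi_t = pi_c + difference
    z = norm.ppf(1.0 - alpha_one_sided) + norm.ppf(target_power)
    n = z * z * (pi_c * (1.0 - pi_c) + pi_t * (1.0 - pi_t)) / (difference * difference)
    return int(math.ceil(n - 1e-12))


def predictive_prob_success(draws: PosteriorDraws, future: FutureTrialSpec) -> float:
    """Posterior-predictive probability of phase III success.

    The expected frequentist power of the future trial, averaged over the
    joint posterior of (pi_t, pi_c): each posterior draw contributes the
    one-sided normal-approximation power of the future trial at that pair
    of response rates.  For quadrature draws the average is the exact
    double sum over the product grid.
    """
    _require(draws.n_draws >= 1, "draws must be non-empty")
    n = future.n_per_arm
    a = future.alpha_one_sided
    if draws.source == "mcmc":
        powers = two_proportion_power(draws.pi_treatment, draws.pi_control, n, a)
        return float(np.mean(powers))
    pmat = two_proportion_power(draws.pi_treatment[None, :], draws.pi_control[:, None], n, a)
    return float(draws.weights_control @ pmat @ draws.weights_treatment)


# --------------------------------------------------------------------------
# Operating-characteristics simulation study
# --------------------------------------------------------------------------


def simulate_trial_data(scenario: Scenario, design: TrialDesign, seed) -> tuple[ArmCount, ArmCount]:
    """Generate one trial's counts under the scenario's true rates.

    Y_c ~ Binomial(n_c, pi_c_true) and Y_t ~ Binomial(n_t, pi_c_true +
    effect), independently.  ``seed`` may be an int or a
    ``numpy.random.SeedSequence``; identical seeds give identical counts.
    """
    rng = np.random.default_rng(seed)
    y_c = int(rng.binomial(design.n_control, scenario.true_pi_control))
    y_t = int(rng.binomial(design.n_treatment, scenario.true_pi_treatment))
    return (
        ArmCount(successes=y_c, n=design.n_control, arm_label="control"),
        ArmCount(successes=y_t, n=design.n_treatment, arm_label="treatment"),
    )


def _trial_seed_seq(root_seed: int, scenario_index: int, sim_index: int) -> np.random.SeedSequence:
    # Deterministic per-simulation stream, independent of execution order.
    return np.random.SeedSequence(root_seed, spawn_key=(scenario_index, sim_index))


def run_simulation_study(
    scenarios: Sequence[Scenario],
    design: TrialDesign,
    future: FutureTrialSpec,
    settings: McmcSettings,
    root_seed: int,
    *,
    evaluation_mode: str = "mcmc",
    n_grid: int = DEFAULT_N_GRID,
) -> list[OperatingCharacteristics]:
    """Estimate the design's operating characteristics by simulation.

    For each scenario, ``scenario.n_simulations`` trials are generated,
    each is evaluated with the futility rule and the predictive probability
    of phase III success, and the results are aggregated with Monte Carlo
    standard errors.  Per-trial records are attached to each
    ``OperatingCharacteristics`` (``.trials``) so aggregates can be
    recomputed without re-running.

    Each simulation draws its data seed and its MCMC seed from a dedicated
    child of ``root_seed`` keyed by (scenario index, simulation index), so
    results do not depend on execution order.

    ``evaluation_mode="quadrature"`` replaces per-trial MCMC with the
    deterministic grid posterior — exact at the per-trial level and much
    faster; ``"mcmc"`` is the reference default.
    """
    _require(len(scenarios) >= 1, "at least one scenario required")
    _require(evaluation_mode in ("mcmc", "quadrature"), "evaluation_mode must be 'mcmc' or 'quadrature'")
    results: list[OperatingCharacteristics] = []
    for s_idx, scenario in enumerate(scenarios):
        rows = []
        logger.info("scenario %s: %d simulations (%s mode)", scenario.label, scenario.n_simulations, evaluation_mode)
        for i in range(scenario.n_simulations):
            ss = _trial_seed_seq(root_seed, s_idx, i)
            ss_data, ss_mcmc = ss.spawn(2)
            arms = simulate_trial_data(scenario, design, ss_data)
            try:
                if evaluation_mode == "mcmc":
                    trial_settings = dataclasses.replace(
                        settings, seed=int(ss_mcmc.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
                    )
                    dec = evaluate_trial(arms, design, trial_settings, mode="mcmc", future=future)
                else:
                    dec = evaluate_trial(arms, design, mode="quadrature", future=future, n_grid=n_grid)
            except Exception:
                logger.exception("simulation %d of scenario %s failed; aborting scenario", i, scenario.label)
                raise
            rows.append(
                {
                    "scenario": scenario.label,
                    "sim_index": i,
                    "y_c": dec.y_control,
                    "n_c": dec.n_control,
                    "y_t": dec.y_treatment,
                    "n_t": dec.n_treatment,
                    "p_futility": dec.p_futility,
                    "declared_futile": dec.declared_futile,
                    "pred_prob_success": dec.pred_prob_success,
                }
            )
            if (i + 1) % 100 == 0:
                logger.info("scenario %s: %d/%d done", scenario.label, i + 1, scenario.n_simulations)
        trials = pd.DataFrame(rows)
        results.append(_aggregate(scenario, trials))
    return results


def _aggregate(scenario: Scenario, trials: pd.DataFrame) -> OperatingCharacteristics:
    n = len(trials)
    k = int(trials["declared_futile"].sum())
    p = k / n
    se_p = math.sqrt(p * (1.0 - p) / n)
    pred = trials["pred_prob_success"].to_numpy(dtype=float)
    mean_pred = float(pred.mean())
    se_pred = float(pred.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    not_fut = pred[~trials["declared_futile"].to_numpy(dtype=bool)]
    cond = float(not_fut.mean()) if not_fut.size else float("nan")
    return OperatingCharacteristics(
        scenario=scenario,
        prop_futile=p,
        prop_futile_mc_se=se_p,
        mean_predictive_prob=mean_pred,
        mean_predictive_prob_conditional_not_futile=cond,
        mc_se_predictive=se_pred,
        n_simulations_run=n,
        trials=trials,
    )


def summarize(ocs: Sequence[OperatingCharacteristics], design: TrialDesign | None = None) -> pd.DataFrame:
    """Tidy per-scenario summary table of the operating characteristics.

    One row per scenario: proportion of trials declared futile with its
    Monte Carlo SE, and the mean predictive probability of phase III
    success both unconditionally and restricted to trials not declared
    futile.  Design parameters are echoed when ``design`` is given.
    """
    _require(len(ocs) >= 1, "at least one OperatingCharacteristics required")
    rows = []
    for oc in ocs:
        row = {
            "scenario": oc.scenario.label,
            "true_pi_control": oc.scenario.true_pi_control,
            "true_effect": oc.scenario.true_effect,
            "n_simulations": oc.n_simulations_run,
            "prop_futile": oc.prop_futile,
            "prop_futile_mc_se": oc.prop_futile_mc_se,
            "mean_predictive_prob": oc.mean_predictive_prob,
            "mean_predictive_prob_conditional_not_futile": oc.mean_predictive_prob_conditional_not_futile,
            "mc_se_predictive": oc.mc_se_predictive,
        }
        if design is not None:
            row.update(
                n_total=design.n_total,
                delta=design.delta,
                futility_threshold=design.futility_threshold,
                prior_mu_control=design.prior_control.mu,
                prior_sigma_control=design.prior_control.sigma,
                prior_mu_treatment=design.prior_treatment.mu,
                prior_sigma_treatment=design.prior_treatment.sigma,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Configuration files and report writing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one simulation run, file round-trippable."""

    design: TrialDesign = field(default_factory=TrialDesign)
    scenarios: tuple[Scenario, ...] = (
        Scenario(true_pi_control=0.30, true_effect=0.0, label="effect_0"),
        Scenario(true_pi_control=0.30, true_effect=0.09, label="effect_0.09"),
    )
    future: FutureTrialSpec = field(default_factory=FutureTrialSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    root_seed: int = 0
    evaluation_mode: str = "mcmc"
    output_dir: str = "futilitysim-output"

    def __post_init__(self) -> None:
        _require(self.evaluation_mode in ("mcmc", "quadrature"), "evaluation_mode must be 'mcmc' or 'quadrature'")
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        _require(len(self.scenarios) >= 1, "at least one scenario required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["allocation"] = list(self.design.allocation)
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            design_d = dict(d.get("design", {}))
            if design_d.get("allocation") is not None:
                design_d["allocation"] = tuple(design_d["allocation"])
            for key in ("prior_control", "prior_treatment"):
                if key in design_d and isinstance(design_d[key], dict):
                    design_d[key] = PriorSpec(**design_d[key])
            return cls(
                design=TrialDesign(**design_d),
                scenarios=tuple(Scenario(**s) for s in d.get("scenarios", [])) or cls().scenarios,
                future=FutureTrialSpec(**d.get("future", {})),
                mcmc=McmcSettings(**d.get("mcmc", {})),
                root_seed=int(d.get("root_seed", 0)),
                evaluation_mode=d.get("evaluation_mode", "mcmc"),
                output_dir=d.get("output_dir", "futilitysim-output"),
            )
        except TypeError as exc:  # unknown field names
            raise ValueError(f"malformed configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    """Read a YAML (or JSON, a YAML subset) run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    _require(isinstance(data, dict), "configuration file must contain a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    _atomic_write_text(path, yaml.safe_dump(config.to_dict(), sort_keys=False))


def draws_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Columnar (arm, draw_index, theta, pi) view for diagnostics CSVs."""
    frames = []
    for arm, theta, pi in (
        ("control", draws.theta_control, draws.pi_control),
        ("treatment", draws.theta_treatment, draws.pi_treatment),
    ):
        frames.append(pd.DataFrame({"arm": arm, "draw_index": np.arange(theta.size), "theta": theta, "pi": pi}))
    return pd.concat(frames, ignore_index=True)


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


_CSV_FLOAT_FMT = "%.6f"


def write_study_outputs(
    ocs: Sequence[OperatingCharacteristics],
    config: RunConfig,
    output_dir,
) -> dict:
    """Write the study's report files; returns the paths written.

    Files: ``trials.csv`` (per-trial records), ``summary.csv`` and
    ``summary.json`` (per-scenario aggregates), ``manifest.json`` (full
    config echo + package version).  Writes are atomic.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = pd.concat([oc.trials for oc in ocs], ignore_index=True)
    summary = summarize(ocs, config.design)
    paths = {
        "trials": out / "trials.csv",
        "summary_csv": out / "summary.csv",
        "summary_json": out / "summary.json",
        "manifest": out / "manifest.json",
    }
    _atomic_write_text(paths["trials"], trials.to_csv(index=False, float_format=_CSV_FLOAT_FMT))
    _atomic_write_text(paths["summary_csv"], summary.to_csv(index=False, float_format=_CSV_FLOAT_FMT))
    _atomic_write_text(paths["summary_json"], summary.to_json(orient="records", indent=2))
    from . import __version__

    manifest = {"package": "futilitysim", "version": __version__, "config": config.to_dict()}
    _atomic_write_text(paths["manifest"], json.dumps(manifest, indent=2))
    return {k: str(v) for k, v in paths.items()}
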