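"""Core Bayesian model: link, posterior density, sampler, quadrature oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.stats import norm

import futilitysim as fs
from conftest import batch_means_se


# ------------------------------------------------------------------ link


@pytest.mark.parametrize(
    "theta, expected, tol",
    [
        (0.0, 0.5, 0.0),
        (40.0, 1.0, 1e-12),
        # closed form exp(2)/(1+exp(2)), computed here independently of expit
        (2.0, math.exp(2.0) / (1.0 + math.exp(2.0)), 1e-15),
        (-2.0, 1.0 - math.exp(2.0) / (1.0 + math.exp(2.0)), 1e-15),
    ],
)
def test_inverse_logit_values(theta, expected, tol):
    assert fs.inverse_logit(theta) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
def test_inverse_logit_rejects_nonfinite(bad):
    with pytest.raises(ValueError):
        fs.inverse_logit(bad)


@given(st.floats(-700, 700))
@hyp_settings(derandomize=True)
def test_inverse_logit_bounded_and_monotone(theta):
    p = fs.inverse_logit(theta)
    assert 0.0 <= p <= 1.0
    assert fs.inverse_logit(theta + 1.0) >= p


# ------------------------------------------------- log posterior density


def test_armcount_requires_positive_n():
    with pytest.raises(ValueError):
        fs.ArmCount(successes=0, n=0)


def test_prior_term_is_full_normal_log_density():
    # at theta=0 the binomial term is identical, so the difference between two
    # priors is the difference of the normal log-densities at 0
    arm = fs.ArmCount(successes=5, n=10)
    diff = fs.log_posterior_theta(0.0, arm, fs.PriorSpec(0.0, 2.0)) - fs.log_posterior_theta(
        0.0, arm, fs.PriorSpec(0.0, 1000.0)
    )
    expected = norm.logpdf(0.0, 0.0, 2.0) - norm.logpdf(0.0, 0.0, 1000.0)
    assert diff == pytest.approx(expected, abs=1e-12)


def test_log_posterior_matches_grid_oracle_argmax():
    # independently coded density, maximized on a dense grid
    arm = fs.ArmCount(successes=50, n=250)
    prior = fs.PriorSpec(0.0, 2.0)
    grid = np.linspace(-10.0, 10.0, 200001)
    oracle = 50 * grid - 250 * np.log1p(np.exp(grid)) + norm.logpdf(grid, 0.0, 2.0)
    theta_star = grid[np.argmax(oracle)]
    vals = np.array([fs.log_posterior_theta(t, arm, prior) for t in grid[:: 100]])
    assert grid[::100][np.argmax(vals)] == pytest.approx(theta_star, abs=0.02)
    # and the two densities agree pointwise up to the dropped binomial constant
    probe = np.array([-3.0, -1.0, 0.0, 1.5])
    ours = np.array([fs.log_posterior_theta(t, arm, prior) for t in probe])
    theirs = 50 * probe - 250 * np.log1p(np.exp(probe)) + norm.logpdf(probe, 0.0, 2.0)
    assert np.allclose(ours, theirs, atol=1e-10)


def test_log_posterior_finite_for_extreme_theta():
    arm = fs.ArmCount(successes=250, n=250)
    prior = fs.PriorSpec()
    for t in (-500.0, -50.0, 50.0, 500.0):
        assert math.isfinite(fs.log_posterior_theta(t, arm, prior))


# ------------------------------------------------------------ quadrature


def test_quadrature_weights_normalize():
    q = fs.quadrature_posterior(fs.ArmCount(50, 250), fs.PriorSpec(), n_grid=2001)
    assert abs(q.weights.sum() - 1.0) < 1e-12


def test_quadrature_flat_prior_symmetry():
    # nearly flat prior, symmetric data: posterior mean of pi is ~ 0.5
    q = fs.quadrature_posterior(fs.ArmCount(5, 10), fs.PriorSpec(0.0, 1000.0), n_grid=4001)
    assert q.mean_pi == pytest.approx(0.5, abs=1e-3)


def test_quadrature_mean_matches_importance_sampling_oracle():
    # independent oracle: self-normalized importance sampling with a wide
    # normal proposal over theta
    arm = fs.ArmCount(50, 250)
    prior = fs.PriorSpec(0.0, 2.0)
    rng = np.random.default_rng(7)
    prop_mu, prop_sd = math.log(50.5 / 200.5), 0.5
    theta = rng.normal(prop_mu, prop_sd, size=400_000)
    logw = (
        50 * theta
        - 250 * np.log1p(np.exp(theta))
        + norm.logpdf(theta, 0.0, 2.0)
        - norm.logpdf(theta, prop_mu, prop_sd)
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    pi = 1.0 / (1.0 + np.exp(-theta))
    is_mean = float(np.sum(w * pi))
    is_se = float(np.sqrt(np.sum(w**2 * (pi - is_mean) ** 2)))
    q = fs.quadrature_posterior(arm, prior, n_grid=2001)
    assert abs(q.mean_pi - is_mean) < 3 * max(is_se, 1e-6)


def test_quadrature_rejects_coarse_grid():
    with pytest.raises(ValueError):
        fs.quadrature_posterior(fs.ArmCount(5, 10), fs.PriorSpec(), n_grid=50)


def test_tight_prior_overrides_data():
    # sigma -> 0: posterior concentrates at the prior mean whatever the data
    prior = fs.PriorSpec(mu=1.0, sigma=1e-4)
    for y in (0, 100, 200):
        q = fs.quadrature_posterior(fs.ArmCount(y, 200), prior, n_grid=2001)
        assert q.mean_pi == pytest.approx(fs.inverse_logit(1.0), abs=1e-3)


def test_diffuse_prior_recovers_frequentist_estimate():
    q = fs.quadrature_posterior(fs.ArmCount(80, 200), fs.PriorSpec(0.0, 1000.0), n_grid=4001)
    assert abs(q.mean_pi - 80 / 200) < 0.01


# ---------------------------------------------------------------- sampler


def _arms(y_c, y_t, n=250):
    return (
        fs.ArmCount(y_c, n, "control"),
        fs.ArmCount(y_t, n, "treatment"),
    )


def test_sampler_reproducible_bit_identical(design, settings):
    d1 = fs.sample_posterior(_arms(75, 98), design, settings)
    d2 = fs.sample_posterior(_arms(75, 98), design, settings)
    assert np.array_equal(d1.theta_control, d2.theta_control)
    assert np.array_equal(d1.theta_treatment, d2.theta_treatment)


def test_sampler_retains_expected_count(design, settings):
    d = fs.sample_posterior(_arms(75, 98), design, settings)
    assert d.n_draws == settings.n_retained == 1500
    assert np.all((d.pi_control > 0) & (d.pi_control < 1))


def test_degenerate_chain_settings_rejected():
    with pytest.raises(ValueError):
        fs.McmcSettings(n_burnin=1000, n_total_samples=1000)


def test_symmetric_data_centers_difference_at_zero(design, settings):
    d = fs.sample_posterior(_arms(75, 75), design, settings)
    diff = d.pi_treatment - d.pi_control
    se = batch_means_se(diff)
    assert abs(diff.mean()) < 3 * se


def test_extreme_data_orders_arms(design, settings):
    d = fs.sample_posterior(_arms(0, 250), design, settings)
    assert d.pi_treatment.mean() > d.pi_control.mean()


def test_sampler_mean_matches_quadrature(design, settings):
    d = fs.sample_posterior(_arms(75, 98), design, settings)
    q = fs.quadrature_posterior(fs.ArmCount(98, 250, "treatment"), design.prior_treatment)
    se = batch_means_se(d.pi_treatment)
    assert abs(d.pi_treatment.mean() - q.mean_pi) < 3 * se


def test_sampler_acceptance_rate_in_healthy_range(design, settings):
    d = fs.sample_posterior(_arms(75, 98), design, settings)
    for rate in d.acceptance_rates.values():
        assert 0.1 < rate < 0.7


# ------------------------------------------------- futility probability


def test_futility_probability_delta_one_is_certain(design):
    d = fs.quadrature_joint(_arms(75, 98), design)
    assert fs.posterior_prob_futility(d, 1.0) == pytest.approx(1.0, abs=1e-9)


def test_futility_probability_symmetric_exceeds_half(design):
    d = fs.quadrature_joint(_arms(75, 75), design)
    assert fs.posterior_prob_futility(d, 0.09) > 0.5


def test_futility_probability_mcmc_agrees_with_quadrature(design, settings):
    arms = _arms(75, 75)
    mc = fs.sample_posterior(arms, design, settings)
    p_mc = fs.posterior_prob_futility(mc, 0.09)
    p_q = fs.posterior_prob_futility(fs.quadrature_joint(arms, design), 0.09)
    se = batch_means_se((mc.pi_treatment - mc.pi_control < 0.09).astype(float))
    assert abs(p_mc - p_q) < 3 * max(se, 1e-4)


def test_futility_monotone_on_count_lattice(design):
    # decreasing in Y_t, increasing in Y_c and in delta
    n = 40
    base = fs.posterior_prob_futility(
        fs.quadrature_joint((fs.ArmCount(12, n, "control"), fs.ArmCount(14, n, "treatment")), design), 0.09
    )
    for y_t in range(10, 20):
        joint = fs.quadrature_joint((fs.ArmCount(12, n, "control"), fs.ArmCount(y_t, n, "treatment")), design)
        p_hi = fs.posterior_prob_futility(joint, 0.09)
        joint_next = fs.quadrature_joint(
            (fs.ArmCount(12, n, "control"), fs.ArmCount(y_t + 1, n, "treatment")), design
        )
        assert fs.posterior_prob_futility(joint_next, 0.09) <= p_hi
        assert fs.posterior_prob_futility(joint, 0.12) >= p_hi
    for y_c in range(8, 16):
        a = fs.posterior_prob_futility(
            fs.quadrature_joint((fs.ArmCount(y_c, n, "control"), fs.ArmCount(14, n, "treatment")), design), 0.09
        )
        b = fs.posterior_prob_futility(
            fs.quadrature_joint((fs.ArmCount(y_c + 1, n, "control"), fs.ArmCount(14, n, "treatment")), design), 0.09
        )
        assert b >= a
    assert 0.0 < base < 1.0


def test_empty_draws_rejected():
    with pytest.raises(ValueError):
        fs.PosteriorDraws(
            theta_control=np.array([]),
            theta_treatment=np.array([]),
            pi_control=np.array([]),
            pi_treatment=np.array([]),
        )


# ------------------------------------------------------- trial decision


def test_futility_declaration_is_strict(design):
    arms = _arms(75, 75)
    dec = fs.evaluate_trial(arms, design, mode="quadrature")
    # re-evaluating with the threshold set exactly at the computed probability
    # must NOT declare futility (strict >); just below it must
    at = fs.TrialDesign(futility_threshold=dec.p_futility)
    assert fs.evaluate_trial(arms, at, mode="quadrature").declared_futile is False
    below = fs.TrialDesign(futility_threshold=dec.p_futility - 1e-6)
    assert fs.evaluate_trial(arms, below, mode="quadrature").declared_futile is True


def test_extreme_harm_declares_futility(design):
    dec = fs.evaluate_trial(_arms(250, 0), design, mode="quadrature")
    assert dec.p_futility > 0.999
    assert dec.declared_futile


def test_evaluate_requires_settings_in_mcmc_mode(design):
    with pytest.raises(ValueError):
        fs.evaluate_trial(_arms(75, 75), design, None, mode="mcmc")


def test_draws_frame_layout(design, settings):
    d = fs.sample_posterior(_arms(75, 98), design, settings)
    frame = fs.draws_to_frame(d)
    assert list(frame.columns) == ["arm", "draw_index", "theta", "pi"]
    assert len(frame) == 2 * d.n_draws
    np.testing.assert_allclose(frame["pi"], 1 / (1 + np.exp(-frame["theta"])))
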