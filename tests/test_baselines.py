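"""Classical likelihood-free baselines, the relative-KL metric, the
genetic-algorithm objective score, and posterior predictive checks."""

import numpy as np
import pytest

from mechsbi.baselines import (AbcConfig, ibea_objective, mcmc_reference,
                               posterior_predictive_check, rejection_abc,
                               relative_kl, scaled_distance, smc_abc)
from mechsbi.priors import Gaussian, PriorSpec
from mechsbi.toys import ConjugateToySpec, generate_conjugate_fixture


@pytest.fixture(scope="module")
def toy_1d():
    return generate_conjugate_fixture(ConjugateToySpec(dim=1))


_IDENT = lambda raw: raw  # noqa: E731


# ---------------------------------------------------------------------------
# rejection ABC


def test_rejection_abc_small_tolerance_recovers_posterior_variance(toy_1d):
    sim, prior, _ = toy_1d
    cfg = AbcConfig(tolerance=0.1, population_size=100)
    theta, d = rejection_abc(sim, _IDENT, prior, [0.0], cfg,
                             budget=40000, seed=0)
    assert theta.shape[0] > 500
    assert theta.var() == pytest.approx(0.5, abs=0.05)
    assert np.all(d < 0.1)


def test_rejection_abc_infinite_tolerance_returns_the_prior(toy_1d):
    from scipy import stats
    sim, prior, _ = toy_1d
    cfg = AbcConfig(tolerance=np.inf, population_size=100)
    theta, _ = rejection_abc(sim, _IDENT, prior, [0.0], cfg,
                             budget=5000, seed=1)
    ref = prior.sample(5000, 99)
    assert stats.ks_2samp(theta[:, 0], ref[:, 0]).statistic < 0.03


def test_rejection_abc_deterministic_simulator_respects_tolerance():
    prior = PriorSpec(kind="uniform", lower=[-1.0], upper=[1.0])

    def sim(theta, seeds):
        return np.atleast_2d(theta)
    sim.batch = True
    cfg = AbcConfig(tolerance=0.1, population_size=10)
    theta, _ = rejection_abc(sim, _IDENT, prior, [0.2], cfg,
                             budget=2000, seed=2)
    assert np.all(np.abs(theta[:, 0] - 0.2) < 0.1)


def test_rejection_abc_budget_must_cover_population():
    prior = PriorSpec(kind="uniform", lower=[0.0], upper=[1.0])
    with pytest.raises(ValueError):
        rejection_abc(lambda t, s: t, _IDENT, prior, [0.5],
                      AbcConfig(population_size=100), budget=10, seed=0)


# ---------------------------------------------------------------------------
# SMC ABC


def test_smc_abc_recovers_posterior_variance(toy_1d):
    sim, prior, _ = toy_1d
    cfg = AbcConfig(population_size=1000, n_generations=3)
    pop = smc_abc(sim, _IDENT, prior, [0.0], cfg, budget=20000, seed=0)
    mean = np.average(pop.theta[:, 0], weights=pop.weights)
    var = np.average((pop.theta[:, 0] - mean) ** 2, weights=pop.weights)
    assert var == pytest.approx(0.5, abs=0.1)
    assert pop.weights.sum() == pytest.approx(1.0)
    assert pop.effective_sample_size() > 10


def test_smc_single_generation_equals_rejection_at_initial_tolerance(toy_1d):
    sim, prior, _ = toy_1d
    cfg = AbcConfig(population_size=200, n_generations=1)
    pop = smc_abc(sim, _IDENT, prior, [0.0], cfg, budget=2000, seed=3)
    theta_rej, _ = rejection_abc(sim, _IDENT, prior, [0.0],
                                 AbcConfig(population_size=200),
                                 budget=2000, seed=pop_seed(3))
    np.testing.assert_array_equal(np.sort(pop.theta[:, 0]),
                                  np.sort(theta_rej[:, 0]))
    np.testing.assert_allclose(pop.weights, 1.0 / 200)


def pop_seed(seed):
    # the first SMC generation uses the first generated sub-seed
    return int(np.random.SeedSequence(seed).generate_state(1)[0])


def test_smc_tolerances_are_non_increasing(toy_1d):
    sim, prior, _ = toy_1d
    cfg = AbcConfig(population_size=300, n_generations=4)
    pop = smc_abc(sim, _IDENT, prior, [0.0], cfg, budget=8000, seed=4)
    assert np.all(np.diff(pop.tolerances) <= 0)


# ---------------------------------------------------------------------------
# relative KL


def test_relative_kl_is_zero_for_the_reference_itself():
    ref = Gaussian([0.0], [[1.0]])
    prior = Gaussian([0.0], [[25.0]])
    s = ref.sample(5000, 0)
    est = relative_kl(s, ref.log_prob, ref.log_prob, prior.log_prob)
    assert est.value == pytest.approx(0.0, abs=1e-12)


def test_relative_kl_is_one_for_the_prior_as_candidate():
    ref = Gaussian([0.0], [[1.0]])
    prior = Gaussian([0.0], [[25.0]])
    s = ref.sample(5000, 1)
    est = relative_kl(s, ref.log_prob, prior.log_prob, prior.log_prob)
    assert est.value == pytest.approx(1.0, abs=1e-12)


def test_relative_kl_matches_closed_form_gaussian_arithmetic():
    ref = Gaussian([0.0], [[1.0]])
    cand = Gaussian([1.0], [[1.0]])
    prior = Gaussian([0.0], [[100.0]])
    s = ref.sample(200000, 2)
    est = relative_kl(s, ref.log_prob, cand.log_prob, prior.log_prob)
    kl_ref_cand = 0.5  # mean shift of 1 at unit variance
    kl_ref_prior = 0.5 * (np.log(100.0) + 1.0 / 100.0 - 1.0)
    assert est.value == pytest.approx(kl_ref_cand / kl_ref_prior, abs=0.02)


def test_relative_kl_rejects_nonpositive_denominator():
    ref = Gaussian([0.0], [[1.0]])
    s = ref.sample(100, 3)
    with pytest.raises(FloatingPointError):
        relative_kl(s, ref.log_prob, ref.log_prob, ref.log_prob)


# ---------------------------------------------------------------------------
# genetic-algorithm objective score


def test_identical_features_score_zero():
    x = np.arange(7.0)
    scores, total = ibea_objective(x, x, np.ones(7))
    assert total == 0.0
    np.testing.assert_array_equal(scores, 0.0)


def test_one_sigma_deviation_scores_one():
    x_o = np.zeros(3)
    sigma = np.array([2.0, 4.0, 8.0])
    x = np.array([2.0, 0.0, 0.0])
    scores, total = ibea_objective(x, x_o, sigma)
    np.testing.assert_allclose(scores, [1.0, 0.0, 0.0])
    assert total == 1.0


def test_scores_invariant_to_joint_rescaling():
    rng = np.random.default_rng(0)
    x, x_o = rng.normal(size=7), rng.normal(size=7)
    sigma = rng.uniform(0.5, 2.0, size=7)
    s1, _ = ibea_objective(x, x_o, sigma)
    s2, _ = ibea_objective(10 * x, 10 * x_o, 10 * sigma)
    np.testing.assert_allclose(s1, s2)


def test_zero_sigma_rejected():
    with pytest.raises(ValueError):
        ibea_objective(np.ones(2), np.zeros(2), np.array([1.0, 0.0]))


# ---------------------------------------------------------------------------
# MCMC reference


def test_mcmc_standard_normal_moments():
    target = Gaussian([0.0], [[1.0]])
    s, acc = mcmc_reference(target.log_prob, [0.5], n_samples=100000, seed=2)
    assert abs(s.mean()) < 0.05
    assert s.var() == pytest.approx(1.0, abs=0.1)
    assert 0.1 < acc < 0.6


def test_mcmc_correlated_2d_target():
    target = Gaussian([1.0, -1.0], [[1.0, 0.8], [0.8, 1.0]])
    s, _ = mcmc_reference(target.log_prob, [0.0, 0.0], n_samples=40000,
                          seed=3)
    np.testing.assert_allclose(s.mean(axis=0), [1.0, -1.0], atol=0.1)
    assert np.corrcoef(s.T)[0, 1] == pytest.approx(0.8, abs=0.1)


def test_mcmc_requires_finite_start():
    prior = PriorSpec(kind="uniform", lower=[0.0], upper=[1.0])
    with pytest.raises(ValueError):
        mcmc_reference(prior.log_prob, [2.0], n_samples=10, seed=0)


def test_mcmc_is_reproducible():
    target = Gaussian([0.0], [[1.0]])
    a, _ = mcmc_reference(target.log_prob, [0.0], n_samples=500, seed=7)
    b, _ = mcmc_reference(target.log_prob, [0.0], n_samples=500, seed=7)
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# posterior predictive checks


def test_predictive_interval_covers_observation(conjugate_bundle):
    post = conjugate_bundle["posterior"]
    res = posterior_predictive_check(post, conjugate_bundle["simulator"],
                                     conjugate_bundle["extractor"],
                                     conjugate_bundle["x_o"], n=400, seed=0)
    # x_o inside the central 99% predictive interval in both dimensions
    assert np.all(res["rank"] > 0.005 * res["n_valid"])
    assert np.all(res["rank"] < 0.995 * res["n_valid"])


def test_point_mass_posterior_with_deterministic_simulator():
    class Point:
        def sample(self, n, rng):
            return np.tile([[0.3, -0.7]], (n, 1))

    def sim(theta, seeds):
        return np.atleast_2d(theta)
    sim.batch = True
    res = posterior_predictive_check(Point(), sim, _IDENT, [0.3, -0.7],
                                     n=50, seed=1)
    np.testing.assert_allclose(res["mean"], [0.3, -0.7])
    np.testing.assert_allclose(res["sd"], 0.0, atol=1e-12)


def test_predictive_check_requires_enough_draws(conjugate_bundle):
    with pytest.raises(ValueError):
        posterior_predictive_check(conjugate_bundle["posterior"],
                                   conjugate_bundle["simulator"],
                                   conjugate_bundle["extractor"],
                                   conjugate_bundle["x_o"], n=5)


def test_scaled_distance_weights_features():
    d = scaled_distance([[2.0, 0.0]], [0.0, 0.0], scale=[2.0, 1.0])
    assert d[0] == pytest.approx(1.0)
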