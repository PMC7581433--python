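"""Shared fixtures.

Expensive artifacts (trained estimators, reference posteriors, simulation
tables) are session-scoped and shared across test modules so the suite
stays within a desk-scale compute budget.
"""

import numpy as np
import pytest

from mechsbi import (ConjugateToySpec, MdnConfig, TrainConfig,
                     generate_conjugate_fixture, run_snpe)


@pytest.fixture(scope="session")
def conjugate_bundle():
    """2-D conjugate-Gaussian toy with a trained single-round posterior.

    Prior N(0, I), simulator x = theta + eps with eps ~ N(0, I); the
    analytic posterior at x_o is N(x_o/2, I/2).  SNPE: 3000 simulations,
    one round, Gaussian posterior family (single-component MDN).
    """
    spec = ConjugateToySpec(dim=2)
    simulator, prior, posterior_fn = generate_conjugate_fixture(spec)
    extractor = lambda raw: raw  # noqa: E731 - features are the raw draw
    config = MdnConfig(n_params=2, n_features=2, n_components=1,
                       hidden_layer_sizes=[50, 50], seed=0)
    x_o = np.zeros(2)
    posterior = run_snpe(prior, simulator, extractor, x_o, rounds=1,
                         n_per_round=3000, estimator_config=config, seed=1,
                         train_config=TrainConfig(max_epochs=500, patience=40))
    return {
        "spec": spec,
        "simulator": simulator,
        "extractor": extractor,
        "prior": prior,
        "posterior_fn": posterior_fn,
        "x_o": x_o,
        "posterior": posterior,
        "config": config,
    }


@pytest.fixture(scope="session")
def hh_bundle():
    """Amortized HH inference fixtures: one 20k-simulation table and three
    single-Gaussian estimators conditioned on 1, 4 and all 7 features."""
    from mechsbi.density import train_estimator
    from mechsbi.hh import (hh_features, hh_prior, make_hh_simulator,
                            simulate_hh)
    from mechsbi.snpe import run_simulations
    from mechsbi.table import SimulationTable

    prior = hh_prior()
    simulator, extractor = make_hh_simulator()
    table = run_simulations(prior, simulator, extractor, 20000, seed=101)
    tc = TrainConfig(max_epochs=250, patience=25)
    estimators = {}
    subsets = {1: [0], 4: [0, 1, 2, 3], 7: list(range(7))}
    for k, idx in subsets.items():
        sub = SimulationTable(table.theta, table.x[:, idx],
                              table.round_index, table.valid, table.seeds)
        cfg = MdnConfig(n_params=8, n_features=k, n_components=1, seed=0)
        estimators[k] = train_estimator(sub, config=cfg, train_config=tc)

    theta_spiker = np.array([50.0, 5.0, 0.1, 0.07, 600.0, 60.0, 0.1, 70.0])
    x_spiker = hh_features(simulate_hh(theta_spiker[None, :], seed=1234)[0])
    theta_quiet = np.array([2.0, 8.0, 0.3, 0.3, 1000.0, 60.0, 0.05, 70.0])
    x_quiet = hh_features(simulate_hh(theta_quiet[None, :], seed=55)[0])
    return {
        "prior": prior,
        "simulator": simulator,
        "extractor": extractor,
        "table": table,
        "estimators": estimators,
        "subsets": subsets,
        "theta_spiker": theta_spiker,
        "x_spiker": x_spiker,
        "theta_quiet": theta_quiet,
        "x_quiet": x_quiet,
    }


@pytest.fixture(scope="session")
def glm_bundle():
    """Temporal-GLM comparison fixtures: observation, exact-likelihood MCMC
    reference, SNPE posterior (10^4 simulations, Gaussian family) and an
    SMC-ABC population at the same budget."""
    from mechsbi.baselines import AbcConfig, mcmc_reference, smc_abc
    from mechsbi.encoding import (TemporalGlmParams, make_temporal_design,
                                  make_temporal_glm_simulator,
                                  simulate_temporal_glm, sta_summary,
                                  temporal_glm_log_likelihood,
                                  temporal_glm_prior)
    from mechsbi.priors import Gaussian

    design = make_temporal_design(seed=0)
    prior = temporal_glm_prior()
    theta_true = prior.sample(1, np.random.default_rng(42))[0]
    spikes = simulate_temporal_glm(
        TemporalGlmParams(theta_true[1:], theta_true[0]), design, seed=99)
    N, sta, _ = sta_summary(spikes, design)
    x_o = np.concatenate([[N], sta])

    def log_post(th):
        return (temporal_glm_log_likelihood(th, spikes, design)
                + prior.log_prob(th))

    ref_samples, _ = mcmc_reference(log_post, np.zeros(10),
                                    n_samples=20000, seed=1, thin=2)
    reference = Gaussian(ref_samples.mean(0),
                         np.cov(ref_samples.T) + 1e-9 * np.eye(10))

    simulator, extractor = make_temporal_glm_simulator(design)
    cfg = MdnConfig(n_params=10, n_features=10, n_components=1, seed=0)
    snpe_posterior = run_snpe(prior, simulator, extractor, x_o, rounds=1,
                              n_per_round=10000, estimator_config=cfg, seed=5,
                              train_config=TrainConfig(max_epochs=300,
                                                       patience=30))
    smc_pop = smc_abc(simulator, extractor, prior, x_o,
                      AbcConfig(population_size=200, n_generations=5),
                      budget=10000, seed=6)
    return {
        "design": design,
        "prior": prior,
        "theta_true": theta_true,
        "spikes": spikes,
        "x_o": x_o,
        "log_post": log_post,
        "ref_samples": ref_samples,
        "reference": reference,
        "snpe_posterior": snpe_posterior,
        "smc_pop": smc_pop,
        "simulator": simulator,
        "extractor": extractor,
    }


@pytest.fixture(scope="session")
def omni_basis():
    """PCA feature basis fit on 150 prior-predictive channel responses."""
    from mechsbi.omnimodel import (fit_pca_basis, omnimodel_prior,
                                   simulate_protocols)
    prior = omnimodel_prior()
    theta = prior.sample(150, np.random.default_rng(0))
    return fit_pca_basis(simulate_protocols(theta, seed=42))


@pytest.fixture(scope="session")
def omni_amortized(omni_basis):
    """Amortized channel-inference network: a four-component MDN trained
    on 20k prior-predictive simulations of the 55 PCA features."""
    from mechsbi.density import train_estimator
    from mechsbi.omnimodel import make_omnimodel_simulator, omnimodel_prior
    from mechsbi.snpe import run_simulations
    prior = omnimodel_prior()
    simulator, extractor = make_omnimodel_simulator(omni_basis)
    table = run_simulations(prior, simulator, extractor, 20000, seed=1)
    cfg = MdnConfig(n_params=8, n_features=55, n_components=4,
                    hidden_layer_sizes=[180, 180], seed=0)
    estimator = train_estimator(table, config=cfg,
                                train_config=TrainConfig(max_epochs=250,
                                                         patience=30))
    return {"prior": prior, "estimator": estimator, "extractor": extractor,
            "table": table}


@pytest.fixture(scope="session")
def stg_screen():
    """1000 prior draws through the pyloric circuit at desk scale."""
    from mechsbi.snpe import run_simulations
    from mechsbi.stg import make_stg_simulator, stg_prior
    simulator, extractor = make_stg_simulator()
    return run_simulations(stg_prior(), simulator, extractor, 1000, seed=7)
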