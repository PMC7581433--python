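"""Classical likelihood-free baselines and validation metrics.

Rejection ABC and SMC-ABC accept simulations whose summary features fall
within a tolerance of the observation under a scaled Euclidean distance.
A generic adaptive random-walk Metropolis sampler provides reference
posteriors for models with tractable likelihoods.  The relative error in
Kullback–Leibler divergence,

.. math::
    \\frac{D_{KL}(p_{ref}(\\theta|x)\\,\\|\\,\\hat p(\\theta|x))}
         {D_{KL}(p_{ref}(\\theta|x)\\,\\|\\,p(\\theta))},

ranges from 0 (perfect recovery) to 1 (no better than the prior) and is
estimated by Monte Carlo over reference-posterior samples.  The
genetic-algorithm objective score is the per-feature absolute deviation in
units of the feature's prior-predictive standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .priors import Gaussian, PriorSpec
from .snpe import run_simulations

__all__ = [
    "AbcConfig",
    "KlEstimate",
    "scaled_distance",
    "rejection_abc",
    "smc_abc",
    "SmcPopulation",
    "relative_kl",
    "ibea_objective",
    "mcmc_reference",
    "posterior_predictive_check",
]


@dataclass
class AbcConfig:
    """Distance scaling and acceptance settings for ABC."""

    scale: np.ndarray | float = 1.0  # per-feature scale factors
    tolerance: float | None = None  # accept d < tolerance; None -> quantile
    quantile: float = 0.5  # acceptance quantile per SMC generation
    population_size: int = 100
    n_generations: int = 4


def scaled_distance(x, x_o, scale=1.0) -> np.ndarray:
    """Euclidean distance after dividing each feature by its scale factor."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_o = np.asarray(x_o, dtype=float).ravel()
    d = (x - x_o) / np.asarray(scale, dtype=float)
    return np.sqrt(np.sum(d * d, axis=1))


def _simulate_features(simulator, extractor, proposal, n, seed, prior=None):
    table = run_simulations(proposal, simulator, extractor, n, seed,
                            prior=prior)
    return table.theta, table.x, table.valid


def rejection_abc(simulator, feature_extractor, prior: PriorSpec, x_o,
                  config: AbcConfig, budget: int, seed: int):
    """Draw `budget` prior simulations; keep parameters whose features are
    within tolerance of `x_o` (or the `population_size` closest when no
    tolerance is set).  Returns ``(accepted_thetas, distances)``."""
    if budget < config.population_size:
        raise ValueError("budget must cover at least one population")
    theta, x, valid = _simulate_features(simulator, feature_extractor, prior,
                                         budget, seed)
    theta, x = theta[valid], x[valid]
    d = scaled_distance(x, x_o, config.scale)
    if config.tolerance is not None:
        keep = d < config.tolerance
        if not np.any(keep):
            warnings.warn("rejection ABC: zero acceptances at the given tolerance")
        return theta[keep], d[keep]
    order = np.argsort(d)[:config.population_size]
    return theta[order], d[order]


@dataclass
class SmcPopulation:
    theta: np.ndarray
    weights: np.ndarray
    tolerances: list
    n_simulations: int

    def effective_sample_size(self) -> float:
        return 1.0 / np.sum(self.weights ** 2)

    def gaussian_fit(self) -> Gaussian:
        mean = np.average(self.theta, axis=0, weights=self.weights)
        cov = np.cov(self.theta.T, aweights=self.weights)
        return Gaussian(mean, np.atleast_2d(cov))


def smc_abc(simulator, feature_extractor, prior: PriorSpec, x_o,
            config: AbcConfig, budget: int, seed: int) -> SmcPopulation:
    """Sequential Monte Carlo ABC (population Monte Carlo scheme).

    Generation one is rejection ABC; each later generation resamples the
    previous population, perturbs with a Gaussian kernel of twice the
    weighted population covariance, and accepts below a tolerance set at
    the acceptance quantile of the previous generation's distances.  Stops
    early on budget exhaustion or population collapse (ESS < 10).
    """
    if config.n_generations < 1:
        raise ValueError("need at least one generation")
    ss = np.random.SeedSequence(seed)
    gen_seeds = ss.generate_state(config.n_generations + 1)
    rng = np.random.default_rng(ss.spawn(1)[0])
    npop = config.population_size
    per_gen = max(npop, budget // config.n_generations)

    theta, d = rejection_abc(simulator, feature_extractor, prior, x_o,
                             config, per_gen, int(gen_seeds[0]))
    w = np.full(theta.shape[0], 1.0 / max(theta.shape[0], 1))
    used = per_gen
    eps_hist = [float(np.max(d)) if d.size else np.inf]

    for g in range(1, config.n_generations):
        if used + npop > budget:
            break
        eps = float(np.quantile(d, config.quantile))
        cov = 2.0 * np.atleast_2d(np.cov(theta.T, aweights=w))
        cov += 1e-12 * np.eye(cov.shape[0])
        chol = np.linalg.cholesky(cov)
        kernel = Gaussian(np.zeros(theta.shape[1]), cov)
        new_theta, new_d = [], []
        sims_this_gen = 0
        while len(new_theta) < npop and used + sims_this_gen < budget:
            m = min(npop, budget - used - sims_this_gen)
            anc = theta[rng.choice(theta.shape[0], size=m, p=w)]
            prop = anc + rng.standard_normal((m, theta.shape[1])) @ chol.T
            inside = prior.support_mask(prop)
            prop = prop[inside]
            if prop.size == 0:
                sims_this_gen += m
                continue
            _, xs, vs = _simulate_features(
                simulator, feature_extractor, _FixedSamples(prop),
                prop.shape[0], int(gen_seeds[g]) + sims_this_gen)
            sims_this_gen += m
            dd = scaled_distance(xs[vs], x_o, config.scale)
            acc = dd < eps
            new_theta.extend(prop[vs][acc])
            new_d.extend(dd[acc])
        used += sims_this_gen
        if len(new_theta) < 2:
            warnings.warn("SMC-ABC: generation produced too few acceptances; stopping")
            break
        theta_new = np.asarray(new_theta)[:npop]
        d = np.asarray(new_d)[:npop]
        # importance weights: prior over kernel-mixture density
        log_k = np.empty((theta_new.shape[0], theta.shape[0]))
        for j in range(theta.shape[0]):
            log_k[:, j] = kernel.log_prob(theta_new - theta[j])
        mix = np.log(w)[None, :] + log_k
        m = mix.max(axis=1, keepdims=True)
        log_mix = (np.log(np.exp(mix - m).sum(axis=1)) + m[:, 0])
        log_w = prior.log_prob(theta_new) - log_mix
        log_w -= log_w.max()
        w = np.exp(log_w)
        w /= w.sum()
        theta = theta_new
        eps_hist.append(eps)
        if 1.0 / np.sum(w ** 2) < 10:
            warnings.warn("SMC-ABC: effective sample size collapsed; stopping")
            break
    else:
        pass
    if w.sum() == 0:
        raise RuntimeError("SMC-ABC produced an empty population")
    return SmcPopulation(theta, w / w.sum(), eps_hist, used)


class _FixedSamples:
    """Proposal that returns a pre-drawn batch (internal SMC helper)."""

    def __init__(self, theta):
        self.theta = np.atleast_2d(theta)

    def sample(self, n, rng):
        return self.theta[:n]


@dataclass
class KlEstimate:
    value: float
    se: float
    n: int


def relative_kl(ref_samples, ref_log_density, candidate_log_density,
                prior_log_density) -> KlEstimate:
    """Monte-Carlo estimate of relative KL error over reference samples."""
    s = np.atleast_2d(np.asarray(ref_samples, dtype=float))
    lr = np.asarray(ref_log_density(s), dtype=float)
    lc = np.asarray(candidate_log_density(s), dtype=float)
    lp = np.asarray(prior_log_density(s), dtype=float)
    num_terms = lr - lc
    den_terms = lr - lp
    den = float(np.mean(den_terms))
    if den <= 0:
        raise FloatingPointError("relative KL undefined: non-positive "
                                 "reference-to-prior divergence")
    ratio_terms = num_terms / den
    value = float(np.mean(num_terms)) / den
    se = float(np.std(ratio_terms, ddof=1) / np.sqrt(s.shape[0]))
    return KlEstimate(value, se, s.shape[0])


def ibea_objective(x_sim, x_o, sigma):
    """Per-feature objective scores ``|x_sim_j - x_o_j| / sigma_j`` and
    their sum (the genetic-algorithm fitness)."""
    x_sim = np.asarray(x_sim, dtype=float).ravel()
    x_o = np.asarray(x_o, dtype=float).ravel()
    sigma = np.asarray(sigma, dtype=float).ravel()
    if np.any(sigma <= 0):
        raise ValueError("feature standard deviations must be positive")
    scores = np.abs(x_sim - x_o) / sigma
    return scores, float(scores.sum())


def mcmc_reference(log_posterior, init, n_samples: int, seed: int,
                   burn_in: int | None = None, thin: int = 1,
                   initial_scale: float = 0.5):
    """Adaptive random-walk Metropolis sampling of a tractable log-posterior.

    The proposal covariance adapts to the running sample covariance during
    burn-in (scaled 2.38^2/d), with a global scale tuned toward an
    acceptance rate of ~0.3.  Returns ``(samples, acceptance_rate)``.
    """
    init = np.atleast_1d(np.asarray(init, dtype=float))
    d = init.size
    lp0 = float(np.atleast_1d(log_posterior(init[None, :]))[0])
    if not np.isfinite(lp0):
        raise ValueError("log-posterior must be finite at the initial point")
    burn = burn_in if burn_in is not None else max(500, n_samples // 2)
    total = burn + n_samples * thin
    rng = np.random.default_rng(seed)
    cov = np.eye(d) * initial_scale ** 2
    chol = np.linalg.cholesky(cov)
    scale = 1.0
    cur, lp_cur = init.copy(), lp0
    keep = np.empty((n_samples, d))
    acc = 0
    recent_acc = 0
    mean_run = cur.copy()
    cov_run = np.eye(d) * 1e-6
    kept = 0
    for t in range(total):
        prop = cur + scale * (chol @ rng.standard_normal(d))
        lp_prop = float(np.atleast_1d(log_posterior(prop[None, :]))[0])
        if np.log(rng.uniform()) < lp_prop - lp_cur:
            cur, lp_cur = prop, lp_prop
            acc += 1
            recent_acc += 1
        # running moments for adaptation
        delta = cur - mean_run
        mean_run += delta / (t + 2)
        cov_run += (np.outer(delta, cur - mean_run) - cov_run) / (t + 2)
        if t < burn and (t + 1) % 100 == 0:
            rate = recent_acc / 100
            recent_acc = 0
            scale *= np.exp(0.5 * (rate - 0.3))
            if t > 200:
                chol = np.linalg.cholesky(
                    2.38 ** 2 / d * cov_run + 1e-10 * np.eye(d))
            if t + 1 >= 1000 and acc == 0:
                raise RuntimeError("MCMC: zero acceptances over 1000 proposals")
        if t >= burn and (t - burn) % thin == 0 and kept < n_samples:
            keep[kept] = cur
            kept += 1
    return keep[:kept], acc / total


def posterior_predictive_check(posterior, simulator, feature_extractor, x_o,
                               n: int, seed: int = 0):
    """Simulate from `n` posterior draws and summarize each feature.

    Returns a dict with per-feature predictive mean, SD, and the rank of
    the observed feature among the predictive samples (0..n_valid).
    """
    if n < 10:
        raise ValueError("need at least 10 posterior draws")
    table = run_simulations(posterior, simulator, feature_extractor, n, seed)
    if table.n_valid == 0:
        raise RuntimeError("posterior predictive check: all draws invalid")
    x = table.x[table.valid]
    x_o = np.asarray(x_o, dtype=float).ravel()
    rank = np.sum(x < x_o[None, :], axis=0)
    return {
        "mean": x.mean(axis=0),
        "sd": x.std(axis=0),
        "rank": rank,
        "n_valid": int(x.shape[0]),
    }
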