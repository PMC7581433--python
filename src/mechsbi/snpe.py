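"""Sequential neural posterior estimation.

The loop: draw parameters from a proposal (round one: the prior), simulate,
reduce to summary features, train a conditional density estimator on all
rounds' valid rows by importance-weighted maximum likelihood, and — for
multi-round inference — focus the next round's proposal on the current
posterior at the observation.  Importance weights ``w_j = p(theta_j) /
p_tilde(theta_j)`` correct for sampling from a proposal rather than the
prior (the SNPE-B loss); in round one all weights are one.

With a single round the trained network is amortized: it performs inference
for any observation covered by the prior via a forward pass.

SNPE-A's post-hoc correction and SNPE-C's classifier loss are documented
extension points (``proposal_correction`` hook), not implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density import ConditionalDensityEstimator, TrainConfig, train_estimator
from .priors import PriorSpec
from .table import SimulationTable

__all__ = [
    "run_simulations",
    "importance_weights",
    "run_snpe",
    "PosteriorEstimate",
]

_MAX_REJECTION_TRIES = 10_000


def run_simulations(proposal, simulator, feature_extractor, n: int, seed: int,
                    round_index: int = 1, prior: PriorSpec | None = None
                    ) -> SimulationTable:
    """Sample `n` parameters from `proposal`, simulate, extract features.

    `simulator` maps ``(theta_batch, per_row_seeds)`` to a sequence of raw
    outputs (set ``simulator.batch = False`` for per-row callables taking
    ``(theta_row, seed)``).  Rows whose simulation raises or whose feature
    vector contains non-finite entries are flagged invalid, not dropped.
    If `prior` is given, proposal draws are rejected until they fall inside
    its support.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    row_seeds = ss.generate_state(n).astype(np.uint32)
    theta = _sample_in_support(proposal, n, rng, prior)
    log_prop = np.atleast_1d(proposal.log_prob(theta)) if hasattr(proposal, "log_prob") \
        else np.zeros(n)

    raws: list = [None] * n
    errors = 0
    if getattr(simulator, "batch", True):
        try:
            raws = list(simulator(theta, row_seeds))
        except Exception:
            errors = n
    else:
        for i in range(n):
            try:
                raws[i] = simulator(theta[i], int(row_seeds[i]))
            except Exception:
                errors += 1

    dim_x = None
    feats = [None] * n
    for i, raw in enumerate(raws):
        if raw is None:
            continue
        try:
            f = np.asarray(feature_extractor(raw), dtype=float).ravel()
        except Exception:
            continue
        feats[i] = f
        dim_x = f.size if dim_x is None else dim_x
    if dim_x is None:
        warnings.warn("all simulations failed feature extraction")
        dim_x = 1
    x = np.full((n, dim_x), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, f in enumerate(feats):
        if f is not None and f.size == dim_x:
            x[i] = f
            valid[i] = np.all(np.isfinite(f))
    table = SimulationTable(theta, x, np.full(n, round_index), valid, row_seeds,
                            log_prop)
    table.meta = {"simulator": getattr(simulator, "name", repr(simulator)),
                  "extractor": getattr(feature_extractor, "name",
                                       repr(feature_extractor)),
                  "failed": errors}
    return table


def _sample_in_support(proposal, n, rng, prior: PriorSpec | None):
    """Draw from the proposal, rejecting draws outside the prior support."""
    theta = np.atleast_2d(proposal.sample(n, rng))
    if prior is None:
        return theta
    bad = ~prior.support_mask(theta)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > _MAX_REJECTION_TRIES:
            raise RuntimeError("proposal rejection against prior support "
                               "exceeded the retry cap")
        theta[bad] = np.atleast_2d(proposal.sample(int(bad.sum()), rng))
        bad = ~prior.support_mask(theta)
    return theta


def importance_weights(thetas, prior, proposal, clip: float | None = None
                       ) -> np.ndarray:
    """SNPE-B weights ``w_j = p(theta_j) / p_tilde(theta_j)``.

    Zero outside the prior support.  A proposal density of zero at a
    sampled parameter is inconsistent and raises.  Optional clipping at
    `clip` (off by default) stabilizes narrow proposals.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    lp = np.atleast_1d(prior.log_prob(thetas))
    lq = np.atleast_1d(proposal.log_prob(thetas))
    inside = lp > -np.inf
    if np.any(~np.isfinite(lq[inside])):
        raise ValueError("proposal density is zero at sampled parameters")
    w = np.zeros(thetas.shape[0])
    w[inside] = np.exp(lp[inside] - lq[inside])
    if clip is not None:
        w = np.minimum(w, clip)
    return w


class PosteriorEstimate:
    """A trained estimator bound to an observation, truncated to the prior
    support: log-probability is -inf outside, and samples are drawn by
    rejection against the support (capped at 10^4 tries per sample)."""

    def __init__(self, estimator: ConditionalDensityEstimator, x_o,
                 prior: PriorSpec, rounds: int = 1,
                 table: SimulationTable | None = None):
        self.estimator = estimator
        self.x_o = np.atleast_1d(np.asarray(x_o, dtype=float))
        self.prior = prior
        self.rounds = rounds
        self.table = table

    def log_prob(self, theta) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        out = np.full(theta.shape[0], -np.inf)
        inside = self.prior.support_mask(theta)
        if np.any(inside):
            out[inside] = self.estimator.log_prob(theta[inside],
                                                  self.x_o[None, :])
        return out

    def grad_log_prob(self, theta) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        _, g = self.estimator.log_prob_and_grad(theta, self.x_o[None, :])
        return g

    def sample(self, n: int, rng) -> np.ndarray:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        out = np.empty((n, self.prior.dim))
        filled = 0
        tries = 0
        while filled < n:
            tries += 1
            if tries > _MAX_REJECTION_TRIES:
                raise RuntimeError("posterior sampling: rejection against "
                                   "prior support exceeded the retry cap")
            draw = self.estimator.sample(self.x_o[None, :], n - filled, rng)
            keep = draw[self.prior.support_mask(draw)]
            out[filled:filled + keep.shape[0]] = keep
            filled += keep.shape[0]
        return out

    # proposal interface (for the next round / diagnostics)
    def support_mask(self, theta):
        return self.prior.support_mask(theta)


@dataclass
class SnpeDiagnostics:
    n_valid_per_round: list
    loss_trace: list


def run_snpe(prior: PriorSpec, simulator, feature_extractor, x_o,
             rounds: int = 1, n_per_round: int | None = None,
             estimator_config=None, seed: int = 0,
             train_config: TrainConfig | None = None,
             weight_clip: float | None = None) -> PosteriorEstimate:
    """Run SNPE for `rounds` rounds of `n_per_round` simulations each.

    Round one proposes from the prior; later rounds propose from the
    current posterior estimate at `x_o` truncated to the prior support.
    Training pools all rounds' valid rows with importance weights.  The
    estimator is warm-started across rounds.
    """
    if rounds < 1 or n_per_round is None or n_per_round < 1:
        raise ValueError("rounds >= 1 and n_per_round >= 1 required")
    x_o = np.atleast_1d(np.asarray(x_o, dtype=float))
    ss = np.random.SeedSequence(seed)
    round_seeds = ss.generate_state(2 * rounds)
    table: SimulationTable | None = None
    estimator = None
    proposal = prior
    posterior = None
    for r in range(1, rounds + 1):
        new = run_simulations(proposal, simulator, feature_extractor,
                              n_per_round, int(round_seeds[2 * (r - 1)]),
                              round_index=r,
                              prior=None if r == 1 else prior)
        table = new if table is None else table.concat(new)
        if table.n_valid == 0:
            raise RuntimeError(
                f"SNPE aborted: no valid simulations after round {r}")
        valid = table.valid
        w = np.exp(np.atleast_1d(prior.log_prob(table.theta[valid]))
                   - table.log_proposal[valid])
        if weight_clip is not None:
            w = np.minimum(w, weight_clip)
        tc = train_config or TrainConfig()
        tc = TrainConfig(**{**vars(tc), "seed": int(round_seeds[2 * r - 1]) % (2 ** 31)})
        estimator = train_estimator(table, weights=w,
                                    config=estimator_config,
                                    train_config=tc,
                                    estimator=estimator)
        posterior = PosteriorEstimate(estimator, x_o, prior, rounds=r,
                                      table=table)
        proposal = posterior
    return posterior
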