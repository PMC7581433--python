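"""Priors, simulation tables, importance weights and the SNPE loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechsbi import (ConjugateToySpec, MdnConfig, TrainConfig,
                     generate_conjugate_fixture, run_snpe)
from mechsbi.priors import Gaussian, PriorSpec, Transform
from mechsbi.snpe import (PosteriorEstimate, importance_weights,
                          run_simulations)


# ---------------------------------------------------------------------------
# priors


def test_uniform_prior_log_prob_and_support():
    p = PriorSpec(kind="uniform", lower=[0.0, -1.0], upper=[2.0, 1.0])
    inside = p.log_prob([[1.0, 0.0]])
    assert inside[0] == pytest.approx(-np.log(4.0))
    assert p.log_prob([[3.0, 0.0]])[0] == -np.inf
    s = p.sample(500, 0)
    assert np.all(p.support_mask(s))


def test_gaussian_prior_matches_scipy():
    from scipy import stats
    p = PriorSpec(kind="gaussian", mean=[1.0, -1.0],
                  cov=[[2.0, 0.3], [0.3, 1.0]])
    pts = np.array([[0.0, 0.0], [1.0, -1.0]])
    ref = stats.multivariate_normal([1.0, -1.0],
                                    [[2.0, 0.3], [0.3, 1.0]]).logpdf(pts)
    np.testing.assert_allclose(p.log_prob(pts), ref)


def test_transformed_prior_density_includes_jacobian():
    """Uniform(0, 2) pushed through log: density of y = log x must be
    e^y/2 on (-inf, log 2) — quadrature normalizes to one."""
    p = PriorSpec(kind="uniform", lower=[0.0], upper=[2.0],
                  transforms=[Transform("log")])
    ys = np.linspace(-12.0, np.log(2.0) - 1e-9, 20001)
    dens = np.exp(p.transformed_log_prob(ys[:, None]))
    assert np.trapezoid(dens, ys) == pytest.approx(1.0, abs=1e-3)
    np.testing.assert_allclose(dens, np.exp(ys) / 2.0, rtol=1e-10)


@settings(max_examples=30, deadline=None)
@given(st.floats(-0.99, 0.99), st.floats(0.01, 10.0))
def test_logit_transform_round_trip(x, width):
    t = Transform("logit", a=-1.0, b=-1.0 + 2 * width)
    val = -1.0 + width * (x + 1.0)  # inside (a, b)
    assert t.inverse(t.forward(val)) == pytest.approx(val, abs=1e-10)


# ---------------------------------------------------------------------------
# run_simulations


def _identity_sim():
    def sim(theta, seeds):
        return np.atleast_2d(theta)
    sim.batch = True
    return sim


def test_identity_simulator_produces_matching_features():
    prior = PriorSpec(kind="uniform", lower=[-1.0], upper=[1.0])
    t = run_simulations(prior, _identity_sim(), lambda r: r, 3, seed=0)
    np.testing.assert_array_equal(t.theta, t.x)
    assert len(t) == 3 and t.n_valid == 3


def test_run_simulations_is_reproducible():
    prior = PriorSpec(kind="uniform", lower=[-1.0, 0.0], upper=[1.0, 2.0])
    a = run_simulations(prior, _identity_sim(), lambda r: r, 10, seed=5)
    b = run_simulations(prior, _identity_sim(), lambda r: r, 10, seed=5)
    np.testing.assert_array_equal(a.theta, b.theta)
    np.testing.assert_array_equal(a.seeds, b.seeds)


def test_failing_rows_are_flagged_invalid_not_dropped():
    prior = PriorSpec(kind="uniform", lower=[-1.0], upper=[1.0])

    def extractor(raw):
        if raw[0] > 0:
            raise RuntimeError("no feature")
        return raw

    t = run_simulations(prior, _identity_sim(), extractor, 50, seed=1)
    assert len(t) == 50
    assert 0 < t.n_valid < 50
    assert np.all(np.isnan(t.x[~t.valid]))


def test_nonfinite_features_mark_row_invalid():
    prior = PriorSpec(kind="uniform", lower=[-1.0], upper=[1.0])
    ext = lambda raw: np.where(raw > 0, np.nan, raw)  # noqa: E731
    t = run_simulations(prior, _identity_sim(), ext, 40, seed=2)
    assert np.all(~t.valid[t.theta[:, 0] > 0])


def test_all_failing_simulator_warns_and_flags_everything():
    prior = PriorSpec(kind="uniform", lower=[-1.0], upper=[1.0])

    def bad(theta, seeds):
        raise RuntimeError("boom")
    bad.batch = True
    with pytest.warns(UserWarning):
        t = run_simulations(prior, bad, lambda r: r, 5, seed=0)
    assert t.n_valid == 0


# ---------------------------------------------------------------------------
# importance weights


def test_weights_are_one_when_proposal_is_prior():
    prior = PriorSpec(kind="gaussian", mean=[0.0], cov=[[1.0]])
    th = prior.sample(20, 0)
    np.testing.assert_allclose(importance_weights(th, prior, prior), 1.0)


def test_weight_outside_prior_box_is_zero():
    prior = PriorSpec(kind="uniform", lower=[0.0], upper=[1.0])
    proposal = Gaussian([0.5], [[1.0]])
    w = importance_weights([[2.0], [0.5]], prior, proposal)
    assert w[0] == 0.0 and w[1] > 0.0


def test_gaussian_density_ratio():
    prior = Gaussian([0.0], [[1.0]])
    proposal = Gaussian([0.0], [[2.0]])
    w = importance_weights([[0.0]], prior, proposal)
    assert w[0] == pytest.approx(np.sqrt(2.0))


def test_weight_clipping():
    prior = Gaussian([0.0], [[1.0]])
    proposal = Gaussian([0.0], [[2.0]])
    w = importance_weights([[0.0]], prior, proposal, clip=1.0)
    assert w[0] == 1.0


# ---------------------------------------------------------------------------
# the SNPE loop on the conjugate toy


def test_single_round_recovers_conjugate_posterior(conjugate_bundle):
    post = conjugate_bundle["posterior"]
    ref = conjugate_bundle["posterior_fn"](conjugate_bundle["x_o"])
    s = post.sample(5000, 0)
    assert np.all(np.abs(s.mean(axis=0) - ref.mean) < 0.1)
    assert np.all(np.abs(s.var(axis=0) - np.diag(ref.cov)) < 0.1)


def test_single_round_table_has_unit_weights_and_round_one(conjugate_bundle):
    table = conjugate_bundle["posterior"].table
    assert np.all(table.round_index == 1)
    prior = conjugate_bundle["prior"]
    w = np.exp(prior.log_prob(table.theta) - table.log_proposal)
    np.testing.assert_allclose(w, 1.0)


def test_amortization_across_observations(conjugate_bundle):
    """The single-round estimator conditions correctly on observations it
    was never trained toward: mean ~ x_o / 2 for any x_o in prior bulk."""
    est = conjugate_bundle["posterior"].estimator
    means = []
    for x_o in ([1.0, 1.0], [-1.0, 0.5]):
        s = est.sample(np.asarray(x_o)[None, :], 4000,
                       np.random.default_rng(0))
        means.append(s.mean(axis=0))
        np.testing.assert_allclose(means[-1], np.asarray(x_o) / 2, atol=0.15)
    assert np.linalg.norm(means[0] - means[1]) > 0.5  # genuinely conditional


def test_posterior_log_prob_truncates_to_prior_support():
    prior = PriorSpec(kind="uniform", lower=[0.0], upper=[1.0])
    est_prior = PriorSpec(kind="uniform", lower=[0.0], upper=[1.0])
    sim = _identity_sim()
    cfg = MdnConfig(n_params=1, n_features=1, n_components=1,
                    hidden_layer_sizes=[20], seed=0)
    post = run_snpe(prior, sim, lambda r: r, [0.5], rounds=1, n_per_round=300,
                    estimator_config=cfg, seed=0,
                    train_config=TrainConfig(max_epochs=30))
    assert post.log_prob([[2.0]])[0] == -np.inf
    inside = post.log_prob([[0.5]])[0]
    assert inside == post.estimator.log_prob([[0.5]], [[0.5]])[0]
    assert np.all(prior.support_mask(post.sample(2000, 0)))


def test_posterior_gradient_matches_finite_differences(conjugate_bundle):
    post = conjugate_bundle["posterior"]
    theta = np.array([[0.3, -0.2]])
    g = post.grad_log_prob(theta)[0]
    eps = 1e-5
    for i in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[0, i] += eps
        tm[0, i] -= eps
        fd = (post.log_prob(tp) - post.log_prob(tm))[0] / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-4)


def test_multi_round_not_worse_than_single_round(conjugate_bundle):
    """Two rounds at matched total budget stay within 0.1 relative KL of
    the single-round result."""
    from mechsbi.baselines import relative_kl
    prior = conjugate_bundle["prior"]
    ref = conjugate_bundle["posterior_fn"](conjugate_bundle["x_o"])
    rs = ref.sample(20000, 123)

    def relkl(post):
        return relative_kl(rs, ref.log_prob, post.log_prob,
                           prior.log_prob).value

    post2 = run_snpe(prior, conjugate_bundle["simulator"],
                     conjugate_bundle["extractor"], conjugate_bundle["x_o"],
                     rounds=2, n_per_round=1500,
                     estimator_config=conjugate_bundle["config"], seed=1,
                     train_config=TrainConfig(max_epochs=500, patience=40))
    assert np.all(post2.table.round_index[post2.table.round_index > 1] == 2)
    assert relkl(post2) <= relkl(conjugate_bundle["posterior"]) + 0.1


def test_snpe_aborts_when_nothing_is_valid():
    prior = PriorSpec(kind="uniform", lower=[0.0], upper=[1.0])

    def sim(theta, seeds):
        return np.full_like(np.atleast_2d(theta), np.nan)
    sim.batch = True
    cfg = MdnConfig(n_params=1, n_features=1, hidden_layer_sizes=[10])
    with pytest.raises(RuntimeError):
        run_snpe(prior, sim, lambda r: r, [0.5], rounds=1, n_per_round=20,
                 estimator_config=cfg, seed=0)
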