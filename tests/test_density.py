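"""Mixture-density networks, masked autoregressive flows, and their
training loop."""

import numpy as np
import pytest
from scipy import stats

from mechsbi._ad import Tensor, tensor
from mechsbi.density import (FlowConfig, MaskedAutoregressiveFlow, MdnConfig,
                             MixtureDensityNetwork, TrainConfig,
                             load_estimator, min_units, train_estimator,
                             weighted_nll)

LOG_STD_NORMAL_AT_0 = -0.5 * np.log(2 * np.pi)  # about -0.9189


# ---------------------------------------------------------------------------
# architecture sizing


@pytest.mark.parametrize("K,n_params,expected", [
    (2, 8, 89),   # two-component mixture over eight parameters
    (1, 1, 2),
    (8, 9, 439),
])
def test_min_units_formula(K, n_params, expected):
    assert min_units(K, n_params) == expected


@pytest.mark.parametrize("K,n_params", [(0, 3), (2, 0), (-1, -1)])
def test_min_units_rejects_nonpositive(K, n_params):
    with pytest.raises(ValueError):
        min_units(K, n_params)


def test_mdn_config_enforces_layer_width_floor():
    with pytest.raises(ValueError):
        MdnConfig(n_params=8, n_features=7, n_components=2,
                  hidden_layer_sizes=[50, 50])  # needs >= 89
    cfg = MdnConfig(n_params=8, n_features=7, n_components=2)
    assert all(h >= 89 for h in cfg.hidden_layer_sizes)


# ---------------------------------------------------------------------------
# forced-parameter oracles


def _forced_standard_mdn(D=1):
    """MDN whose output mixture is a standard normal for every input."""
    mdn = MixtureDensityNetwork(MdnConfig(n_params=D, n_features=1,
                                          n_components=1,
                                          hidden_layer_sizes=[50], seed=0))
    for W, b in mdn.layers:
        W.value[...] = 0.0
        b.value[...] = 0.0
    for W, b in (mdn.head_logits, mdn.head_means, mdn.head_diag,
                 mdn.head_offd):
        W.value[...] = 0.0
        b.value[...] = 0.0
    mdn.head_diag[1].value[...] = np.log(np.e - 1.0)  # softplus -> 1
    return mdn


def test_mdn_unit_gaussian_log_density_at_zero():
    mdn = _forced_standard_mdn()
    lp = mdn.log_prob(np.zeros((1, 1)), np.zeros((1, 1)))
    assert lp[0] == pytest.approx(LOG_STD_NORMAL_AT_0, abs=1e-6)


def test_maf_identity_bijections_reduce_to_base_density():
    maf = MaskedAutoregressiveFlow(FlowConfig(n_params=2, n_features=1,
                                              n_mades=3, seed=0))
    for p in maf.parameters():
        p.value[...] = 0.0
    lp = maf.log_prob(np.zeros((1, 2)), np.zeros((1, 1)))
    assert lp[0] == pytest.approx(2 * LOG_STD_NORMAL_AT_0, abs=1e-6)


def test_mdn_point_mass_limit_sample_mean():
    mdn = _forced_standard_mdn()
    mdn.head_means[1].value[...] = 1.7
    mdn.head_diag[1].value[...] = 1000.0  # tiny variance
    s = mdn.sample(np.zeros((1, 1)), 500, np.random.default_rng(0))
    assert np.abs(s.mean() - 1.7) < 1e-3


def test_mdn_degenerate_scales_raise_on_sampling():
    mdn = _forced_standard_mdn()
    mdn.head_diag[1].value[...] = -500.0  # softplus underflows to zero
    with pytest.raises(FloatingPointError):
        mdn.sample(np.zeros((1, 1)), 10, 0)


def test_mdn_two_component_sampler_matches_direct_mixture():
    """10^4 draws from a forced K=2 MDN against a brute-force mixture
    sampler: KS distance below 0.03 per marginal."""
    D, K = 2, 2
    mdn = MixtureDensityNetwork(MdnConfig(n_params=D, n_features=1,
                                          n_components=K,
                                          hidden_layer_sizes=[50], seed=0))
    for W, b in mdn.layers + [mdn.head_logits, mdn.head_means, mdn.head_diag,
                              mdn.head_offd]:
        W.value[...] = 0.0
        b.value[...] = 0.0
    mdn.head_logits[1].value[:] = [np.log(0.3), np.log(0.7)]
    means = np.array([[-2.0, 0.5], [1.0, -1.0]])
    mdn.head_means[1].value[:] = means.ravel()
    mdn.head_diag[1].value[...] = np.log(np.e - 1.0)  # unit scales
    s = mdn.sample(np.zeros((1, 1)), 10000, np.random.default_rng(1))
    rng = np.random.default_rng(2)
    ks = rng.choice(K, size=10000, p=[0.3, 0.7])
    direct = means[ks] + rng.standard_normal((10000, D))
    for d in range(D):
        dist = stats.ks_2samp(s[:, d], direct[:, d]).statistic
        assert dist < 0.03


def test_sampling_is_reproducible_under_fixed_seed():
    mdn = _forced_standard_mdn()
    a = mdn.sample(np.zeros((1, 1)), 50, 123)
    b = mdn.sample(np.zeros((1, 1)), 50, 123)
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# normalization and invertibility


@pytest.mark.parametrize("kind", ["mdn", "maf"])
def test_trained_conditional_density_normalizes_to_one(kind):
    rng = np.random.default_rng(3)
    x = rng.normal(size=(1500, 1))
    th = x + 0.5 * rng.standard_normal((1500, 1))
    if kind == "mdn":
        cfg = MdnConfig(n_params=1, n_features=1, n_components=2,
                        hidden_layer_sizes=[30], seed=1)
    else:
        cfg = FlowConfig(n_params=1, n_features=1, n_mades=3,
                         hidden_layer_sizes=[24, 24], seed=1)
    est = train_estimator((th, x), config=cfg,
                          train_config=TrainConfig(max_epochs=60, patience=15))
    grid = np.linspace(-8, 8, 1601)[:, None]
    dens = np.exp(est.log_prob(grid, np.array([[0.4]])))
    assert np.trapezoid(dens, grid[:, 0]) == pytest.approx(1.0, abs=0.01)


def test_maf_forward_inverse_round_trip():
    maf = MaskedAutoregressiveFlow(FlowConfig(n_params=4, n_features=2,
                                              n_mades=5, seed=2))
    rng = np.random.default_rng(0)
    theta = rng.normal(size=(20, 4))
    x = rng.normal(size=(20, 2))
    u, _ = maf.forward_transform(theta, x)
    back = maf.inverse_transform(u, x)
    assert np.max(np.abs(back - theta) / np.maximum(np.abs(theta), 1.0)) < 1e-6


def test_made_autoregressive_masking():
    """Perturbing input dimension j leaves outputs for dimensions < j
    bit-identical (strict masks: dimension j itself is also unaffected)."""
    maf = MaskedAutoregressiveFlow(FlowConfig(n_params=5, n_features=2,
                                              n_mades=1, seed=1))
    made = maf.mades[0]
    rng = np.random.default_rng(0)
    z = rng.normal(size=(1, 5))
    xz = np.zeros((1, 2))
    mu0, al0 = made._net(Tensor(z), xz)
    for j in range(5):
        zp = z.copy()
        zp[0, j] += 3.14
        mu, al = made._net(Tensor(zp), xz)
        assert np.array_equal(mu.value[0, :j + 1], mu0.value[0, :j + 1])
        assert np.array_equal(al.value[0, :j + 1], al0.value[0, :j + 1])


# ---------------------------------------------------------------------------
# training


def test_training_recovers_conditional_mean():
    """theta ~ N(x, 1): the fitted conditional mean tracks x on held-out
    conditioning points to within 0.1 on average."""
    rng = np.random.default_rng(4)
    x = rng.normal(size=(8000, 1))
    th = x + rng.standard_normal((8000, 1))
    cfg = MdnConfig(n_params=1, n_features=1, n_components=1,
                    hidden_layer_sizes=[30, 30], seed=0)
    est = train_estimator((th, x), config=cfg,
                          train_config=TrainConfig(max_epochs=300, patience=40))
    held_out = rng.normal(size=(10, 1))
    _, mus, _ = est.mixture_parameters(held_out)
    devs = np.abs(mus[:, 0, 0] - held_out[:, 0])
    assert devs.mean() < 0.1


def test_loss_trace_descends():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(500, 2))
    th = x @ np.array([[1.0, 0.0], [0.5, 1.0]]) + 0.3 * rng.standard_normal((500, 2))
    cfg = MdnConfig(n_params=2, n_features=2, n_components=1,
                    hidden_layer_sizes=[30], seed=0)
    est = train_estimator((th, x), config=cfg,
                          train_config=TrainConfig(max_epochs=40, patience=40))
    assert est.loss_trace[-1] <= est.loss_trace[0]


def test_duplicated_rows_with_half_weight_leave_loss_unchanged():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(40, 1))
    th = rng.normal(size=(40, 1))
    est = _forced_standard_mdn()
    base = weighted_nll(est, th, x, np.ones(40))
    dup = weighted_nll(est, np.vstack([th, th]), np.vstack([x, x]),
                       np.full(80, 0.5))
    assert dup == pytest.approx(base, rel=1e-12)


def test_training_is_bitwise_reproducible():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(300, 1))
    th = x + rng.standard_normal((300, 1))
    outs = []
    for _ in range(2):
        cfg = MdnConfig(n_params=1, n_features=1, n_components=1,
                        hidden_layer_sizes=[20], seed=3)
        est = train_estimator((th, x), config=cfg,
                              train_config=TrainConfig(max_epochs=10, seed=9))
        outs.append(np.concatenate([p.value.ravel() for p in est.parameters()]))
    np.testing.assert_array_equal(outs[0], outs[1])


def test_empty_training_set_raises():
    with pytest.raises(ValueError):
        train_estimator((np.empty((0, 1)), np.empty((0, 1))),
                        config=MdnConfig(n_params=1, n_features=1,
                                         hidden_layer_sizes=[10]))


def test_dimension_mismatch_raises():
    est = _forced_standard_mdn()
    with pytest.raises(ValueError):
        est.log_prob(np.zeros((1, 3)), np.zeros((1, 1)))


# ---------------------------------------------------------------------------
# persistence


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    x = rng.normal(size=(200, 2))
    th = x + rng.standard_normal((200, 2))
    cfg = MdnConfig(n_params=2, n_features=2, n_components=2,
                    hidden_layer_sizes=[20], seed=1)
    est = train_estimator((th, x), config=cfg,
                          train_config=TrainConfig(max_epochs=5))
    path = tmp_path / "ckpt"
    est.save(str(path))
    loaded = load_estimator(str(path))
    pts = rng.normal(size=(5, 2))
    np.testing.assert_allclose(loaded.log_prob(pts, x[:5]),
                               est.log_prob(pts, x[:5]))
    assert (tmp_path / "ckpt.meta.json").exists()
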