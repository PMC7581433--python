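"""Conditional neural density estimation: mixture density networks and
masked autoregressive flows.

Both estimators model a conditional density :math:`q(\\theta\\mid x)` and are
trained by minimizing the (optionally importance-weighted) negative
log-density of simulated pairs :math:`(\\theta_j, x_j)` — the loss
:math:`\\mathcal{L} = \\sum_j w_j\\,(-\\log q(\\theta_j\\mid x_j))`.

Architecture sizing for the MDN follows the rule that each hidden layer
needs at least ``K(1 + N + N(N+1)/2) - 1`` units for a ``K``-component
mixture over ``N`` parameters — the number of outputs required to specify
mixture weights, means and covariance entries (see :func:`min_units`).

Inputs (features and parameters) are z-scored with training-set statistics
before entering the networks; the statistics are stored in the estimator so
log-densities and samples are always expressed in the original parameter
space (the z-scoring Jacobian is accounted for).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular

from ._ad import Tensor, concat, logsumexp, tensor

__all__ = [
    "MdnConfig",
    "FlowConfig",
    "TrainConfig",
    "min_units",
    "MixtureDensityNetwork",
    "MaskedAutoregressiveFlow",
    "build_estimator",
    "train_estimator",
    "load_estimator",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def min_units(K: int, n_params: int) -> int:
    """Minimum hidden units per layer for a K-component MDN over `n_params`.

    A K-component Gaussian mixture over N parameters is specified by
    ``K`` weights (one redundant), ``K*N`` means and ``K*N(N+1)/2``
    covariance entries, hence ``K(1 + N + N(N+1)/2) - 1`` quantities; each
    hidden layer should be at least that wide.
    """
    if K < 1 or n_params < 1:
        raise ValueError("K and n_params must be positive integers")
    N = int(n_params)
    return int(K) * (1 + N + N * (N + 1) // 2) - 1


# ---------------------------------------------------------------------------
# configs


@dataclass
class MdnConfig:
    """Architecture of a mixture density network."""

    n_params: int
    n_features: int
    n_components: int = 1
    hidden_layer_sizes: Sequence[int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_params < 1 or self.n_features < 1:
            raise ValueError("n_params and n_features must be >= 1")
        floor = min_units(self.n_components, self.n_params)
        if self.hidden_layer_sizes is None:
            self.hidden_layer_sizes = [max(floor, 50)] * 2
        self.hidden_layer_sizes = [int(h) for h in self.hidden_layer_sizes]
        if any(h < floor for h in self.hidden_layer_sizes):
            raise ValueError(
                f"hidden layers must have >= {floor} units for "
                f"K={self.n_components}, n_params={self.n_params}"
            )


@dataclass
class FlowConfig:
    """Architecture of a masked autoregressive flow (stack of MADEs)."""

    n_params: int
    n_features: int
    n_mades: int = 5
    hidden_layer_sizes: Sequence[int] = (50, 50)
    log_scale_cap: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_mades < 1:
            raise ValueError("n_mades must be >= 1")
        if self.n_params < 1 or self.n_features < 1:
            raise ValueError("n_params and n_features must be >= 1")
        self.hidden_layer_sizes = [int(h) for h in self.hidden_layer_sizes]


@dataclass
class TrainConfig:
    """Optimization settings: Adam with default settings, early stopping on
    a 10% held-out split."""

    max_epochs: int = 500
    batch_size: int = 100
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    patience: int = 20
    seed: int = 0


# ---------------------------------------------------------------------------
# shared machinery


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    W = tensor(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out)))
    b = tensor(np.zeros(fan_out))
    return W, b


class _TriQuad(Tensor):
    """Fused node computing ``||U^T d||^2`` per row, where U is the
    lower-triangular precision factor assembled from `diag` (n,D) and
    packed strictly-lower entries `offd` (n, D(D-1)/2)."""

    def __init__(self, diff: Tensor, diag: Tensor, offd: Tensor, D: int):
        rows, cols = np.tril_indices(D, k=-1)
        n = diff.value.shape[0]
        U = np.zeros((n, D, D))
        U[:, np.arange(D), np.arange(D)] = diag.value
        U[:, rows, cols] = offd.value
        y = np.einsum("nij,ni->nj", U, diff.value)
        quad = np.sum(y * y, axis=-1)

        def bw(g):
            gy = 2.0 * y * g[:, None]  # d quad / d y
            gdiff = np.einsum("nij,nj->ni", U, gy)
            gU = np.einsum("ni,nj->nij", diff.value, gy)
            gdiag = gU[:, np.arange(D), np.arange(D)]
            goffd = gU[:, rows, cols]
            return gdiff, gdiag, goffd

        super().__init__(quad, (diff, diag, offd), bw)


class ConditionalDensityEstimator:
    """Base class: trainable conditional density q(theta | x).

    Holds architecture config, trainable weights, z-scoring statistics and
    training metadata (loss trace, seed).
    """

    kind = "base"

    def __init__(self, config):
        self.config = config
        self.theta_mean = np.zeros(config.n_params)
        self.theta_std = np.ones(config.n_params)
        self.x_mean = np.zeros(config.n_features)
        self.x_std = np.ones(config.n_features)
        self.loss_trace: list[float] = []
        self.val_trace: list[float] = []
        self.seed = config.seed
        self._params: list[Tensor] = []

    # -- public API ------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return self._params

    def set_normalization(self, theta: np.ndarray, x: np.ndarray) -> None:
        self.theta_mean = theta.mean(axis=0)
        self.theta_std = np.maximum(theta.std(axis=0), 1e-8)
        self.x_mean = x.mean(axis=0)
        self.x_std = np.maximum(x.std(axis=0), 1e-8)

    def _check(self, theta: np.ndarray, x: np.ndarray):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if theta.shape[1] != self.config.n_params:
            raise ValueError(
                f"theta has {theta.shape[1]} columns, expected {self.config.n_params}")
        if x.shape[1] != self.config.n_features:
            raise ValueError(
                f"x has {x.shape[1]} columns, expected {self.config.n_features}")
        if x.shape[0] == 1 and theta.shape[0] > 1:
            x = np.broadcast_to(x, (theta.shape[0], x.shape[1]))
        if theta.shape[0] != x.shape[0]:
            raise ValueError("theta and x row counts differ")
        return theta, x

    def log_prob(self, theta, x) -> np.ndarray:
        theta, x = self._check(theta, x)
        return self.log_prob_t(tensor(theta), x).value

    def log_prob_and_grad(self, theta, x):
        """Log-density and its gradient with respect to theta (per row)."""
        theta, x = self._check(theta, x)
        leaf = tensor(theta)
        lp = self.log_prob_t(leaf, x)
        lp.sum().backward()
        return lp.value, leaf.grad

    # subclasses implement:
    def log_prob_t(self, theta: Tensor, x: np.ndarray) -> Tensor:
        raise NotImplementedError

    def sample(self, x, n: int, rng) -> np.ndarray:
        raise NotImplementedError

    # -- persistence -----------------------------------------------------
    def _state_arrays(self) -> dict:
        arrs = {f"p{i}": p.value for i, p in enumerate(self._params)}
        arrs.update(
            theta_mean=self.theta_mean, theta_std=self.theta_std,
            x_mean=self.x_mean, x_std=self.x_std,
            loss_trace=np.asarray(self.loss_trace),
            val_trace=np.asarray(self.val_trace),
        )
        return arrs

    def save(self, path: str) -> None:
        """Binary checkpoint (`.npz`) plus plain-text metadata header."""
        path = str(path)
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 **self._state_arrays())
        meta = {"kind": self.kind, "seed": int(self.seed),
                "config": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                           for k, v in vars(self.config).items()}}
        with open((path[:-4] if path.endswith(".npz") else path) + ".meta.json",
                  "w") as fh:
            json.dump(meta, fh, indent=1)

    def _load_arrays(self, data) -> None:
        for i, p in enumerate(self._params):
            p.value = np.asarray(data[f"p{i}"])
        self.theta_mean = np.asarray(data["theta_mean"])
        self.theta_std = np.asarray(data["theta_std"])
        self.x_mean = np.asarray(data["x_mean"])
        self.x_std = np.asarray(data["x_std"])
        self.loss_trace = list(data["loss_trace"])
        self.val_trace = list(data["val_trace"])


# ---------------------------------------------------------------------------
# mixture density network


class MixtureDensityNetwork(ConditionalDensityEstimator):
    """Feedforward network whose outputs parameterize a conditional
    Gaussian mixture over the (z-scored) parameters.

    Mixture weights come from normalized exponentials of the weight head;
    each component's Gaussian is parameterized by its mean and a
    lower-triangular precision factor with softplus-positive diagonal, so
    the log-density is an explicit quadratic form.
    """

    kind = "mdn"

    def __init__(self, config: MdnConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        K, D, dx = config.n_components, config.n_params, config.n_features
        self._K, self._D = K, D
        self._n_offd = D * (D - 1) // 2
        sizes = [dx] + list(config.hidden_layer_sizes)
        self.layers = [_init_linear(rng, a, b) for a, b in zip(sizes, sizes[1:])]
        h = sizes[-1]
        self.head_logits = _init_linear(rng, h, K)
        self.head_means = _init_linear(rng, h, K * D)
        self.head_diag = _init_linear(rng, h, K * D)
        self.head_offd = _init_linear(rng, h, K * self._n_offd)
        self._params = [t for pair in
                        self.layers + [self.head_logits, self.head_means,
                                       self.head_diag, self.head_offd]
                        for t in pair]

    # -- forward ---------------------------------------------------------
    def _trunk(self, xz: np.ndarray) -> Tensor:
        h = Tensor(xz)
        for W, b in self.layers:
            h = (h @ W + b).tanh()
        return h

    def _heads(self, h: Tensor):
        K, D = self._K, self._D
        logits = h @ self.head_logits[0] + self.head_logits[1]
        means = h @ self.head_means[0] + self.head_means[1]
        diag = (h @ self.head_diag[0] + self.head_diag[1]).softplus()
        offd = h @ self.head_offd[0] + self.head_offd[1]
        return logits, means, diag, offd

    def log_prob_t(self, theta: Tensor, x: np.ndarray) -> Tensor:
        K, D = self._K, self._D
        xz = (np.atleast_2d(x) - self.x_mean) / self.x_std
        z = (theta - Tensor(self.theta_mean)) * Tensor(1.0 / self.theta_std)
        logits, means, diag, offd = self._heads(self._trunk(xz))
        log_mix_w = logits - logsumexp(logits, axis=-1).reshape(-1, 1)
        comp_terms = []
        for k in range(K):
            mu_k = means[:, k * D:(k + 1) * D]
            dg_k = diag[:, k * D:(k + 1) * D]
            od_k = offd[:, k * self._n_offd:(k + 1) * self._n_offd]
            diff = z - mu_k
            quad = _TriQuad(diff, dg_k, od_k, D)
            logdet = dg_k.log().sum(axis=-1)  # log|det U| = sum log diag
            lp_k = logdet - 0.5 * quad - 0.5 * D * _LOG_2PI
            comp_terms.append((log_mix_w[:, k] + lp_k).reshape(-1, 1))
        mix = logsumexp(concat(comp_terms, axis=-1), axis=-1)
        return mix - float(np.sum(np.log(self.theta_std)))

    # -- mixture parameters and sampling ---------------------------------
    def mixture_parameters(self, x: np.ndarray):
        """Mixture weights, component means and covariances at conditioning
        input `x` (one row), in the original parameter space."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xz = (x - self.x_mean) / self.x_std
        logits, means, diag, offd = self._heads(self._trunk(xz))
        K, D = self._K, self._D
        w = np.exp(logits.value - logits.value.max(axis=-1, keepdims=True))
        w = w / w.sum(axis=-1, keepdims=True)
        rows, cols = np.tril_indices(D, k=-1)
        mus, covs = [], []
        scale = np.diag(self.theta_std)
        for k in range(K):
            U = np.zeros((x.shape[0], D, D))
            U[:, np.arange(D), np.arange(D)] = diag.value[:, k * D:(k + 1) * D]
            U[:, rows, cols] = offd.value[:, k * self._n_offd:(k + 1) * self._n_offd]
            prec = np.einsum("nij,nkj->nik", U, U)  # U U^T
            cov_z = np.linalg.inv(prec)
            mus.append(means.value[:, k * D:(k + 1) * D] * self.theta_std
                       + self.theta_mean)
            covs.append(scale @ cov_z @ scale)
        return w, np.stack(mus, axis=1), np.stack(covs, axis=1)

    def sample(self, x, n: int, rng) -> np.ndarray:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != 1:
            raise ValueError("sample() conditions on a single feature vector")
        xz = (x - self.x_mean) / self.x_std
        logits, means, diag, offd = self._heads(self._trunk(xz))
        K, D = self._K, self._D
        if not np.all(np.isfinite(diag.value)) or np.any(diag.value < 1e-12):
            raise FloatingPointError("degenerate mixture scales; estimator untrained?")
        w = np.exp(logits.value[0] - logits.value[0].max())
        w = w / w.sum()
        rows, cols = np.tril_indices(D, k=-1)
        ks = rng.choice(K, size=n, p=w)
        eps = rng.standard_normal((n, D))
        out = np.empty((n, D))
        for k in range(K):
            m = ks == k
            if not np.any(m):
                continue
            U = np.zeros((D, D))
            U[np.arange(D), np.arange(D)] = diag.value[0, k * D:(k + 1) * D]
            U[rows, cols] = offd.value[0, k * self._n_offd:(k + 1) * self._n_offd]
            mu = means.value[0, k * D:(k + 1) * D]
            # z = mu + U^{-T} eps has covariance (U U^T)^{-1}
            z = mu + solve_triangular(U.T, eps[m].T, lower=False).T
            out[m] = z * self.theta_std + self.theta_mean
        return out


# ---------------------------------------------------------------------------
# masked autoregressive flow


def _made_masks(D: int, hidden: Sequence[int], reverse: bool):
    """Connectivity masks for one MADE (strict autoregressive structure)."""
    deg_in = np.arange(1, D + 1)
    if reverse:
        deg_in = deg_in[::-1]
    degrees = [deg_in]
    for h in hidden:
        hi = max(D - 1, 1)
        degrees.append(1 + (np.arange(h) % hi))
    masks = []
    for d_prev, d_next in zip(degrees[:-1], degrees[1:]):
        masks.append((d_next[None, :] >= d_prev[:, None]).astype(float))
    # output mask: output for dim d depends only on inputs with degree < d
    out_mask = (deg_in[None, :] > degrees[-1][:, None]).astype(float)
    return degrees, masks, out_mask, deg_in


class _Made:
    """One masked autoregressive bijection with conditional inputs."""

    def __init__(self, rng, D, dx, hidden, reverse, cap):
        self.D, self.dx, self.cap = D, dx, cap
        _, self.masks, self.out_mask, self.deg_in = _made_masks(D, hidden, reverse)
        sizes = [D] + list(hidden)
        self.layers = []
        for (a, b) in zip(sizes, sizes[1:]):
            self.layers.append(_init_linear(rng, a, b))
        self.cond_layers = [_init_linear(rng, dx, h) for h in hidden]
        h = sizes[-1]
        self.W_mu = _init_linear(rng, h, D)
        self.W_al = _init_linear(rng, h, D)
        # conditioning inputs are "degree zero": they may feed every output
        # directly, so even the first autoregressive dimension is conditioned
        self.cond_mu = _init_linear(rng, dx, D)
        self.cond_al = _init_linear(rng, dx, D)

    def parameters(self):
        out = []
        for W, b in (self.layers + self.cond_layers
                     + [self.W_mu, self.W_al, self.cond_mu, self.cond_al]):
            out += [W, b]
        return out

    def _net(self, z: Tensor, xz: np.ndarray):
        h = z
        for i, ((W, b), mask) in enumerate(zip(self.layers, self.masks)):
            pre = h @ (W * Tensor(mask)) + b
            Wc, bc = self.cond_layers[i]
            pre = pre + (Tensor(xz) @ Wc + bc)
            h = pre.tanh()
        om = Tensor(self.out_mask)
        xt = Tensor(xz)
        mu = h @ (self.W_mu[0] * om) + (xt @ self.cond_mu[0] + self.cond_mu[1]) \
            + self.W_mu[1]
        raw = h @ (self.W_al[0] * om) + (xt @ self.cond_al[0] + self.cond_al[1]) \
            + self.W_al[1]
        alpha = (raw * (1.0 / self.cap)).tanh() * self.cap  # smooth clamp
        return mu, alpha

    def forward(self, z: Tensor, xz: np.ndarray):
        """Density direction: u = (z - mu(z,x)) * exp(-alpha(z,x))."""
        mu, alpha = self._net(z, xz)
        u = (z - mu) * (-alpha).exp()
        return u, -alpha.sum(axis=-1)

    def inverse(self, u: np.ndarray, xz: np.ndarray) -> np.ndarray:
        """Sampling direction: solve z dim by dim in autoregressive order."""
        z = np.zeros_like(u)
        order = np.argsort(self.deg_in)  # positions in increasing degree
        for pos in order:
            mu, alpha = self._net(Tensor(z), xz)
            z[:, pos] = u[:, pos] * np.exp(alpha.value[:, pos]) + mu.value[:, pos]
        return z


class MaskedAutoregressiveFlow(ConditionalDensityEstimator):
    """Stack of masked autoregressive bijections over a standard-normal
    base, conditioned on features; dimension order reverses between
    bijections."""

    kind = "maf"

    def __init__(self, config: FlowConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.seed)
        D, dx = config.n_params, config.n_features
        self.mades = [
            _Made(rng, D, dx, config.hidden_layer_sizes, reverse=(i % 2 == 1),
                  cap=config.log_scale_cap)
            for i in range(config.n_mades)
        ]
        self._params = [p for m in self.mades for p in m.parameters()]

    def forward_transform(self, theta: np.ndarray, x: np.ndarray):
        """Map parameters to base-space variables; returns (u, log|det J|)."""
        theta, x = self._check(theta, x)
        xz = (x - self.x_mean) / self.x_std
        z = tensor((theta - self.theta_mean) / self.theta_std)
        ld = Tensor(np.zeros(theta.shape[0]))
        for made in self.mades:
            z, step_ld = made.forward(z, xz)
            ld = ld + step_ld
        return z.value, ld.value

    def log_prob_t(self, theta: Tensor, x: np.ndarray) -> Tensor:
        xz = (np.atleast_2d(x) - self.x_mean) / self.x_std
        z = (theta - Tensor(self.theta_mean)) * Tensor(1.0 / self.theta_std)
        logdet = Tensor(np.zeros(z.value.shape[0]))
        for made in self.mades:
            z, ld = made.forward(z, xz)
            logdet = logdet + ld
        base = -0.5 * (z ** 2).sum(axis=-1) - 0.5 * self._D_log2pi()
        return base + logdet - float(np.sum(np.log(self.theta_std)))

    def _D_log2pi(self):
        return self.config.n_params * _LOG_2PI

    def inverse_transform(self, u: np.ndarray, x: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xz = (x - self.x_mean) / self.x_std
        if xz.shape[0] == 1:
            xz = np.broadcast_to(xz, (u.shape[0], xz.shape[1]))
        z = u
        for made in reversed(self.mades):
            z = made.inverse(z, xz)
        return z * self.theta_std + self.theta_mean

    def sample(self, x, n: int, rng) -> np.ndarray:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        u = rng.standard_normal((n, self.config.n_params))
        return self.inverse_transform(u, x)


# ---------------------------------------------------------------------------
# training


def build_estimator(config) -> ConditionalDensityEstimator:
    if isinstance(config, MdnConfig):
        return MixtureDensityNetwork(config)
    if isinstance(config, FlowConfig):
        return MaskedAutoregressiveFlow(config)
    raise TypeError(f"unknown estimator config: {type(config)!r}")


class _Adam:
    """Adaptive-moment gradient descent with default settings."""

    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else 0.0
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weighted_nll(estimator, theta, x, weights) -> float:
    """Weighted negative log-density sum(w * -log q) / sum(w)."""
    lp = estimator.log_prob(theta, x)
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * -lp) / np.sum(w))


def _extract_rows(dataset):
    """Accept a SimulationTable-like object or a (theta, x) pair."""
    if hasattr(dataset, "theta"):
        valid = np.asarray(dataset.valid, dtype=bool)
        return np.asarray(dataset.theta)[valid], np.asarray(dataset.x)[valid], valid
    theta, x = dataset
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return theta, x, np.ones(theta.shape[0], dtype=bool)


def train_estimator(dataset, weights=None, config=None,
                    train_config: TrainConfig | None = None,
                    estimator: ConditionalDensityEstimator | None = None):
    """Fit a conditional density estimator by weighted maximum likelihood.

    Parameters
    ----------
    dataset
        SimulationTable (invalid rows are excluded) or ``(theta, x)`` arrays.
    weights
        Per-row nonnegative weights (aligned with the *valid* rows); defaults
        to all ones.
    config
        ``MdnConfig`` or ``FlowConfig`` — ignored when `estimator` is given
        (warm start).
    train_config
        Optimization settings (Adam, early stopping on a 10% held-out split).
    estimator
        Existing estimator to continue training (e.g. across rounds).
    """
    tc = train_config or TrainConfig()
    theta, x, _ = _extract_rows(dataset)
    n = theta.shape[0]
    if n < 1:
        raise ValueError("empty training set: no valid rows")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != n:
            raise ValueError("weights length does not match number of valid rows")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and nonnegative")

    if estimator is None:
        est = build_estimator(config)
        est.set_normalization(theta, x)
    else:
        est = estimator

    rng = np.random.default_rng(tc.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(tc.validation_fraction * n))) if n >= 10 else 0
    val_idx, trn_idx = perm[:n_val], perm[n_val:]
    if trn_idx.size == 0:
        trn_idx, val_idx = perm, perm[:0]

    opt = _Adam(est.parameters(), lr=tc.learning_rate)
    best_val = np.inf
    best_state = [p.value.copy() for p in est.parameters()]
    stall = 0
    for _epoch in range(tc.max_epochs):
        order = rng.permutation(trn_idx)
        ep_loss, ep_w = 0.0, 0.0
        for start in range(0, order.size, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            lp = est.log_prob_t(tensor(theta[idx]), x[idx])
            wb = w[idx]
            loss = (Tensor(wb) * -lp).sum() * (1.0 / max(wb.sum(), 1e-12))
            loss.backward()
            opt.step()
            ep_loss += float(loss.value) * wb.sum()
            ep_w += wb.sum()
        est.loss_trace.append(ep_loss / max(ep_w, 1e-12))
        if val_idx.size:
            vloss = weighted_nll(est, theta[val_idx], x[val_idx], w[val_idx])
            est.val_trace.append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = [p.value.copy() for p in est.parameters()]
                stall = 0
            else:
                stall += 1
                if stall >= tc.patience:
                    break
    if val_idx.size:
        for p, v in zip(est.parameters(), best_state):
            p.value = v
    return est


def load_estimator(path: str) -> ConditionalDensityEstimator:
    """Rebuild an estimator from a checkpoint written by ``save()``."""
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".meta.json") as fh:
        meta = json.load(fh)
    cfg_cls = {"mdn": MdnConfig, "maf": FlowConfig}[meta["kind"]]
    est = build_estimator(cfg_cls(**meta["config"]))
    with np.load(base + ".npz") as data:
        est._load_arrays(data)
    return est
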