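"""Posterior-geometry analyses.

Three tools for dissecting a (differentiable) posterior over model
parameters:

* **Conditional correlations** — fix all but one or two parameters at a
  conditioning point, evaluate the posterior on an evenly spaced grid over
  the prior range, and compute the Pearson correlation of the normalized
  2-D conditional; averaging the per-condition matrices over
  posterior-sampled conditioning points summarizes pairwise compensation.
* **High-probability paths** — a curve between two parameter sets,
  parameterized by sinusoidal basis functions that pin the endpoints, is
  optimized to minimize the path integral of negative posterior
  log-density times arclength.
* **Orthogonal perturbations** — gradient-projection steps that reduce
  posterior probability as quickly as possible while staying orthogonal to
  the path tangent.

All tools require only `log_prob` (and, for the optimizers,
`grad_log_prob`) on the posterior object, so they work on trained
posterior estimates and analytic test distributions alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConditionalGrid",
    "conditional_grid",
    "conditional_correlation",
    "conditional_moments_1d",
    "average_conditional_corr",
    "path_length",
    "PathParameterization",
    "path_eval",
    "path_loss",
    "optimize_path",
    "orthogonal_step",
    "orthogonal_descent",
]


# ---------------------------------------------------------------------------
# conditional correlations


@dataclass
class ConditionalGrid:
    """Posterior density on an evenly spaced grid over 1 or 2 free
    dimensions, all other parameters fixed at a conditioning point."""

    theta_fixed: np.ndarray
    free_idx: tuple
    axes: list  # one 1-D coordinate array per free dimension
    density: np.ndarray  # shape (n,) or (n, n), nonnegative


def conditional_grid(posterior, theta_fixed, free_idx, lower, upper,
                     n_points: int = 50) -> ConditionalGrid:
    """Evaluate the posterior over a grid in the given free dimension(s)."""
    theta_fixed = np.asarray(theta_fixed, dtype=float).ravel()
    free_idx = tuple(int(i) for i in np.atleast_1d(free_idx))
    if len(free_idx) not in (1, 2):
        raise ValueError("1 or 2 free dimensions required")
    lower = np.asarray(lower, dtype=float).ravel()
    upper = np.asarray(upper, dtype=float).ravel()
    axes = [np.linspace(lower[i], upper[i], n_points) for i in free_idx]
    if len(free_idx) == 1:
        pts = np.tile(theta_fixed, (n_points, 1))
        pts[:, free_idx[0]] = axes[0]
    else:
        A, B = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.tile(theta_fixed, (n_points * n_points, 1))
        pts[:, free_idx[0]] = A.ravel()
        pts[:, free_idx[1]] = B.ravel()
    lp = np.asarray(posterior.log_prob(pts), dtype=float)
    lp = lp - np.max(lp[np.isfinite(lp)]) if np.any(np.isfinite(lp)) else lp
    dens = np.where(np.isfinite(lp), np.exp(lp), 0.0)
    dens = dens.reshape((n_points,) * len(free_idx))
    return ConditionalGrid(theta_fixed, free_idx, axes, dens)


def conditional_correlation(grid: ConditionalGrid) -> float:
    """Pearson correlation of the normalized 2-D conditional density."""
    if len(grid.free_idx) != 2:
        raise ValueError("conditional correlation needs 2 free dimensions")
    p = grid.density
    total = p.sum()
    if total <= 0:
        raise FloatingPointError("conditional density has zero mass on the grid")
    p = p / total
    a, b = grid.axes
    pa, pb = p.sum(axis=1), p.sum(axis=0)
    ma, mb = pa @ a, pb @ b
    va = pa @ (a - ma) ** 2
    vb = pb @ (b - mb) ** 2
    cov = ((a - ma)[:, None] * (b - mb)[None, :] * p).sum()
    return float(cov / np.sqrt(va * vb))


def conditional_moments_1d(grid: ConditionalGrid):
    """Trapezoid-normalized mean and SD of a 1-D conditional."""
    (axis,) = grid.axes
    dens = grid.density
    Z = np.trapezoid(dens, axis)
    if Z <= 0:
        raise FloatingPointError("conditional density has zero mass on the grid")
    dens = dens / Z
    mean = np.trapezoid(axis * dens, axis)
    var = np.trapezoid((axis - mean) ** 2 * dens, axis)
    return float(mean), float(np.sqrt(var))


def average_conditional_corr(posterior, lower, upper, n_conditions: int = 50,
                             seed: int = 0, n_points: int = 50) -> np.ndarray:
    """Mean conditional-correlation matrix over posterior-sampled
    conditioning points; diagonal fixed at one."""
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    rng = np.random.default_rng(seed)
    points = np.atleast_2d(posterior.sample(n_conditions, rng))
    D = points.shape[1]
    acc = np.zeros((D, D))
    for c in range(n_conditions):
        M = np.eye(D)
        for i in range(D):
            for j in range(i + 1, D):
                g = conditional_grid(posterior, points[c], (i, j),
                                     lower, upper, n_points)
                M[i, j] = M[j, i] = conditional_correlation(g)
        acc += M
    return acc / n_conditions


# ---------------------------------------------------------------------------
# high-probability paths


@dataclass
class PathParameterization:
    """Curve gamma(s) between fixed endpoints with sinusoidal wiggles:

    ``gamma(s) = (1-s) theta_s + s theta_g
    + sum_{k<=K} alpha[:,k-1] sin(pi k s) + sum_{k=K+1..2K} alpha[:,k-1] sin^2(pi k s)``

    Every basis function vanishes at s=0 and s=1, so gamma(0)=theta_s and
    gamma(1)=theta_g exactly for any coefficients.
    """

    theta_s: np.ndarray
    theta_g: np.ndarray
    n_basis: int = 2  # K
    alpha: np.ndarray | None = None
    n_points: int = 80

    def __post_init__(self):
        self.theta_s = np.asarray(self.theta_s, dtype=float).ravel()
        self.theta_g = np.asarray(self.theta_g, dtype=float).ravel()
        D = self.theta_s.size
        if self.alpha is None:
            self.alpha = np.zeros((D, 2 * self.n_basis))
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(
            (D, 2 * self.n_basis))


def _basis(path: PathParameterization, s: np.ndarray) -> np.ndarray:
    """Basis matrix B with B[m, k] = k-th basis function at s_m."""
    K = path.n_basis
    s = np.atleast_1d(np.asarray(s, dtype=float))
    cols = [np.sin(np.pi * k * s) for k in range(1, K + 1)]
    cols += [np.sin(np.pi * k * s) ** 2 for k in range(K + 1, 2 * K + 1)]
    B = np.stack(cols, axis=1)
    B[(s == 0.0) | (s == 1.0)] = 0.0  # endpoints pinned exactly
    return B


def path_eval(path: PathParameterization, s) -> np.ndarray:
    """Points gamma(s); shape (len(s), D) (or (D,) for scalar s)."""
    scalar = np.isscalar(s)
    s = np.atleast_1d(np.asarray(s, dtype=float))
    base = (1 - s)[:, None] * path.theta_s + s[:, None] * path.theta_g
    pts = base + _basis(path, s) @ path.alpha.T
    return pts[0] if scalar else pts


def _discretize(path: PathParameterization):
    s = np.linspace(0.0, 1.0, path.n_points)
    pts = path_eval(path, s)
    ds = s[1] - s[0]
    vel = np.gradient(pts, ds, axis=0)  # central differences, one-sided ends
    return s, pts, vel, ds


def path_length(path: PathParameterization) -> float:
    _, pts, vel, ds = _discretize(path)
    return float(np.sum(np.linalg.norm(vel, axis=1)
                        * _quad_weights(path.n_points, ds)))


def _quad_weights(n: int, ds: float) -> np.ndarray:
    """Trapezoid weights: exact for a constant integrand."""
    w = np.full(n, ds)
    w[0] = w[-1] = 0.5 * ds
    return w


def path_loss(path: PathParameterization, posterior) -> float:
    """Discretized integral of -log p(gamma(s)) times speed."""
    _, pts, vel, ds = _discretize(path)
    lp = np.asarray(posterior.log_prob(pts), dtype=float)
    speed = np.linalg.norm(vel, axis=1)
    terms = np.where(np.isfinite(lp), -lp * speed, np.inf * np.ones_like(lp))
    terms = np.where(speed == 0.0, 0.0, terms)
    return float(np.sum(terms * _quad_weights(path.n_points, ds)))


def _path_loss_grad(path: PathParameterization, posterior):
    """Loss and its gradient with respect to the basis coefficients."""
    s, pts, vel, ds = _discretize(path)
    n = path.n_points
    qw = _quad_weights(n, ds)
    lp = np.asarray(posterior.log_prob(pts), dtype=float)
    glp = np.asarray(posterior.grad_log_prob(pts), dtype=float)
    speed = np.linalg.norm(vel, axis=1)
    speed_safe = np.maximum(speed, 1e-12)
    loss = float(np.sum(-lp * speed * qw))
    # d loss / d pts: direct term plus speed dependence through np.gradient
    dL_dpts = -glp * (speed * qw)[:, None]
    w = (-lp * qw)[:, None] * vel / speed_safe[:, None]  # dL/d vel_m
    # adjoint of np.gradient: vel_0=(p1-p0)/ds, vel_m=(p_{m+1}-p_{m-1})/(2ds),
    # vel_{n-1}=(p_{n-1}-p_{n-2})/ds
    adj = np.zeros_like(pts)
    adj[0] -= w[0] / ds
    adj[1] += w[0] / ds
    adj[2:] += w[1:-1] / (2 * ds)
    adj[:-2] -= w[1:-1] / (2 * ds)
    adj[-1] += w[-1] / ds
    adj[-2] -= w[-1] / ds
    dL_dpts = dL_dpts + adj
    B = _basis(path, s)  # (n, 2K)
    grad_alpha = dL_dpts.T @ B  # (D, 2K)
    return loss, grad_alpha


def optimize_path(path: PathParameterization, posterior, steps: int = 2000,
                  learning_rate: float = 1e-3) -> PathParameterization:
    """Gradient descent on the basis coefficients; endpoints never move.

    Keeps the best coefficients seen; aborts early (returning best-so-far)
    if the loss diverges.
    """
    alpha = path.alpha.copy()
    cur = PathParameterization(path.theta_s, path.theta_g, path.n_basis,
                               alpha, path.n_points)
    best_loss, best_alpha = np.inf, alpha.copy()
    for _ in range(steps):
        loss, g = _path_loss_grad(cur, posterior)
        if not np.isfinite(loss):
            break
        if loss < best_loss:
            best_loss, best_alpha = loss, cur.alpha.copy()
        if np.abs(loss) > 1e12:
            break
        cur.alpha = cur.alpha - learning_rate * g
    final_loss = path_loss(cur, posterior)
    if np.isfinite(final_loss) and final_loss < best_loss:
        best_alpha = cur.alpha
    return PathParameterization(path.theta_s, path.theta_g, path.n_basis,
                                best_alpha, path.n_points)


# ---------------------------------------------------------------------------
# orthogonal perturbations


def orthogonal_step(posterior, theta, tangent) -> np.ndarray:
    """One gradient-projection step orthogonal to `tangent`:

    ``delta = -P grad / (grad^T P grad)`` with ``P = I - n n^T / (n^T n)``.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    n = np.asarray(tangent, dtype=float).ravel()
    nn = n @ n
    if nn <= 0:
        raise ValueError("tangent must be nonzero")
    grad = np.asarray(posterior.grad_log_prob(theta[None, :]),
                      dtype=float).ravel()
    Pg = grad - n * (n @ grad) / nn
    denom = grad @ Pg
    if denom <= 1e-300:
        raise FloatingPointError("projected gradient vanished")
    return -Pg / denom


def orthogonal_descent(posterior, theta0, tangent, total_distance: float,
                       max_steps: int = 10_000):
    """Iterate orthogonal steps until the cumulative distance reaches
    `total_distance` (e.g. 1/27 of the high-probability path length).

    Returns the trajectory (including the start point).
    """
    theta = np.asarray(theta0, dtype=float).ravel().copy()
    traj = [theta.copy()]
    travelled = 0.0
    for _ in range(max_steps):
        if travelled >= total_distance:
            break
        try:
            step = orthogonal_step(posterior, theta, tangent)
        except FloatingPointError:
            break
        norm = np.linalg.norm(step)
        if travelled + norm > total_distance:
            step = step * (total_distance - travelled) / norm
            norm = total_distance - travelled
        theta = theta + step
        travelled += norm
        traj.append(theta.copy())
    return np.asarray(traj)
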