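"""Prior specifications and simple analytic distributions.

A :class:`PriorSpec` is either box-uniform or Gaussian over the native
parameter space, with optional per-dimension transforms (identity, log, or
generalized logit with bounds) that map native parameters to an
unconstrained space.  The density on transformed parameters includes the
Jacobian of the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["PriorSpec", "Gaussian", "Transform"]


@dataclass(frozen=True)
class Transform:
    """Per-dimension monotone transform: identity, log, or generalized
    logit ``l_{a,b}(X) = log((X - a) / (b - X))`` mapping (a, b) to R."""

    kind: str = "identity"  # identity | log | logit
    a: float = 0.0
    b: float = 1.0

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x
        if self.kind == "log":
            return np.log(x)
        if self.kind == "logit":
            return np.log((x - self.a) / (self.b - x))
        raise ValueError(self.kind)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y
        if self.kind == "log":
            return np.exp(y)
        if self.kind == "logit":
            s = 1.0 / (1.0 + np.exp(-y))
            return self.a + (self.b - self.a) * s
        raise ValueError(self.kind)

    def log_abs_det_forward(self, x):
        """log |d forward / dx| (adds to densities on the transformed side
        via the inverse-function Jacobian)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return np.zeros_like(x)
        if self.kind == "log":
            return -np.log(x)
        if self.kind == "logit":
            return np.log(self.b - self.a) - np.log(x - self.a) - np.log(self.b - x)
        raise ValueError(self.kind)


class Gaussian:
    """Multivariate Gaussian with sampling, log-density and score."""

    def __init__(self, mean, cov):
        self.mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 0:
            cov = np.eye(self.mean.size) * cov
        elif cov.ndim == 1:
            cov = np.diag(cov)
        self.cov = cov
        self.dim = self.mean.size
        self._mvn = stats.multivariate_normal(self.mean, self.cov)
        self._prec = np.linalg.inv(self.cov)

    def sample(self, n, rng):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return rng.multivariate_normal(self.mean, self.cov, size=n)

    def log_prob(self, theta):
        return np.atleast_1d(self._mvn.logpdf(np.atleast_2d(theta)))

    def grad_log_prob(self, theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return -(theta - self.mean) @ self._prec

    def support_mask(self, theta):
        return np.ones(np.atleast_2d(theta).shape[0], dtype=bool)


@dataclass
class PriorSpec:
    """Box-uniform or Gaussian prior with optional per-dimension transforms."""

    kind: str  # "uniform" | "gaussian"
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    mean: np.ndarray | None = None
    cov: np.ndarray | None = None
    transforms: Sequence[Transform] | None = None

    def __post_init__(self):
        if self.kind == "uniform":
            self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
            self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
            if not (np.all(np.isfinite(self.lower)) and np.all(np.isfinite(self.upper))):
                raise ValueError("uniform prior requires finite bounds")
            if np.any(self.upper <= self.lower):
                raise ValueError("upper bounds must exceed lower bounds")
            self.dim = self.lower.size
        elif self.kind == "gaussian":
            g = Gaussian(self.mean, self.cov)
            self.mean, self.cov, self.dim = g.mean, g.cov, g.dim
            self._gauss = g
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.transforms is not None and len(self.transforms) != self.dim:
            raise ValueError("one transform per dimension required")

    # -- native-space interface -----------------------------------------
    def sample(self, n, rng):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        if self.kind == "uniform":
            return rng.uniform(self.lower, self.upper, size=(n, self.dim))
        return self._gauss.sample(n, rng)

    def support_mask(self, theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if self.kind == "uniform":
            return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)
        return np.ones(theta.shape[0], dtype=bool)

    def log_prob(self, theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if self.kind == "uniform":
            out = np.full(theta.shape[0], -np.inf)
            inside = self.support_mask(theta)
            out[inside] = -np.sum(np.log(self.upper - self.lower))
            return out
        return self._gauss.log_prob(theta)

    # -- transformed-space interface -------------------------------------
    def _tf(self) -> list[Transform]:
        return list(self.transforms or [Transform()] * self.dim)

    def transform(self, theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.column_stack(
            [t.forward(theta[:, i]) for i, t in enumerate(self._tf())])

    def untransform(self, phi):
        phi = np.atleast_2d(np.asarray(phi, dtype=float))
        return np.column_stack(
            [t.inverse(phi[:, i]) for i, t in enumerate(self._tf())])

    def transformed_log_prob(self, phi):
        """Density of the transformed parameters (Jacobian included)."""
        phi = np.atleast_2d(np.asarray(phi, dtype=float))
        theta = self.untransform(phi)
        lp = self.log_prob(theta)
        jac = np.zeros(phi.shape[0])
        for i, t in enumerate(self._tf()):
            jac -= t.log_abs_det_forward(theta[:, i])
        return lp + jac
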