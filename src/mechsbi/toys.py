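"""Synthetic fixtures with closed-form posteriors.

The conjugate-Gaussian toy — prior ``theta ~ N(m0, S0)``, simulator
``x = theta + eps`` with ``eps ~ N(0, Sn)`` — has the analytic posterior

.. math::
    p(\\theta\\mid x_o) = N\\big(S (S_0^{-1} m_0 + S_n^{-1} x_o),\\; S\\big),
    \\quad S = (S_0^{-1} + S_n^{-1})^{-1},

which serves as the oracle for recovery, calibration and relative-KL checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import Gaussian, PriorSpec

__all__ = ["ConjugateToySpec", "generate_conjugate_fixture"]


@dataclass
class ConjugateToySpec:
    dim: int = 2
    prior_mean: np.ndarray | float = 0.0
    prior_cov: np.ndarray | float = 1.0
    noise_cov: np.ndarray | float = 1.0

    def __post_init__(self):
        self.prior_mean = np.broadcast_to(
            np.asarray(self.prior_mean, dtype=float), (self.dim,)).copy()
        self.prior_cov = self._cov(self.prior_cov)
        self.noise_cov = self._cov(self.noise_cov)
        for C in (self.prior_cov, self.noise_cov):
            np.linalg.cholesky(C)  # must be positive definite

    def _cov(self, c):
        c = np.asarray(c, dtype=float)
        if c.ndim == 0:
            return np.eye(self.dim) * float(c)
        if c.ndim == 1:
            return np.diag(c)
        return c


def generate_conjugate_fixture(spec: ConjugateToySpec, seed: int = 0):
    """Return ``(simulator, prior, posterior_fn)`` for the conjugate toy.

    `simulator` follows the batch protocol of :func:`mechsbi.snpe.run_simulations`
    (raw output = the noisy observation itself); `posterior_fn(x_o)` returns
    the analytic posterior as a :class:`mechsbi.priors.Gaussian`.
    """
    spec = spec or ConjugateToySpec()
    prior = PriorSpec(kind="gaussian", mean=spec.prior_mean, cov=spec.prior_cov)
    noise_chol = np.linalg.cholesky(spec.noise_cov)

    def simulator(theta_batch, row_seeds):
        theta_batch = np.atleast_2d(theta_batch)
        out = np.empty_like(theta_batch)
        for i, (th, s) in enumerate(zip(theta_batch, row_seeds)):
            eps = np.random.default_rng(int(s)).standard_normal(spec.dim)
            out[i] = th + noise_chol @ eps
        return out

    simulator.batch = True
    simulator.name = f"conjugate_gaussian_d{spec.dim}"

    P0 = np.linalg.inv(spec.prior_cov)
    Pn = np.linalg.inv(spec.noise_cov)
    S = np.linalg.inv(P0 + Pn)

    def posterior_fn(x_o) -> Gaussian:
        x_o = np.atleast_1d(np.asarray(x_o, dtype=float))
        mean = S @ (P0 @ spec.prior_mean + Pn @ x_o)
        return Gaussian(mean, S)

    return simulator, prior, posterior_fn
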