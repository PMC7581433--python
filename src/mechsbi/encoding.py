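"""Linear-nonlinear encoding models.

Two simulators of stimulus-driven spiking:

* a temporal Bernoulli GLM — a length-9 linear filter plus bias applied to
  white-noise input, spikes in T=100 bins through the logistic link; the
  spike count N and spike-triggered average (STA) are sufficient summary
  features;
* a spatial Poisson GLM — a Gabor-parameterized receptive field applied to
  a white-noise movie, spike counts through the exponential link, with
  log/logit transforms mapping the bounded Gabor parameters to an
  unconstrained space where the prior is Gaussian.

The temporal filter's prior is a zero-mean Gaussian whose covariance
``sigma^2 (F^T F)^{-1}`` penalizes second-order differences (F is the
second-difference operator with Dirichlet boundaries, which makes it
invertible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import Gaussian, PriorSpec, Transform

__all__ = [
    "TemporalGlmParams",
    "SmoothnessPrior",
    "temporal_glm_prior",
    "make_temporal_design",
    "simulate_temporal_glm",
    "sta_summary",
    "temporal_glm_log_likelihood",
    "make_temporal_glm_simulator",
    "GaborParams",
    "gabor_sigma",
    "gabor_filter",
    "simulate_gabor_glm",
    "transform_gabor",
    "untransform_gabor",
    "gabor_prior",
]

FILTER_LENGTH = 9
T_BINS = 100


def _sigmoid(u):
    return 0.5 * (np.tanh(0.5 * u) + 1.0)


@dataclass
class TemporalGlmParams:
    """Length-9 linear filter and bias of the Bernoulli GLM."""

    filt: np.ndarray
    bias: float

    def __post_init__(self):
        self.filt = np.asarray(self.filt, dtype=float).ravel()
        if self.filt.size != FILTER_LENGTH:
            raise ValueError(f"filter must have length {FILTER_LENGTH}")
        if not (np.all(np.isfinite(self.filt)) and np.isfinite(self.bias)):
            raise ValueError("parameters must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([[self.bias], self.filt])


@dataclass
class SmoothnessPrior:
    """Gaussian with covariance ``sigma^2 (F^T F)^{-1}`` where F penalizes
    second-order differences (Dirichlet boundaries keep it invertible)."""

    size: int = FILTER_LENGTH
    scale: float = 1.0

    def __post_init__(self):
        self.F = self.second_difference_operator(self.size)
        FtF = self.F.T @ self.F
        self.cov = self.scale ** 2 * np.linalg.inv(FtF)
        np.linalg.cholesky(self.cov)

    @staticmethod
    def second_difference_operator(n: int) -> np.ndarray:
        F = np.zeros((n, n))
        for i in range(n):
            F[i, i] = -2.0
            if i > 0:
                F[i, i - 1] = 1.0
            if i < n - 1:
                F[i, i + 1] = 1.0
        return F


def temporal_glm_prior(filter_scale: float = 2.0, bias_mean: float = 0.0,
                       bias_sd: float = 1.0) -> PriorSpec:
    """Prior over [bias, filter]: independent Gaussian bias times the
    smoothness prior on the filter coefficients."""
    sp = SmoothnessPrior(scale=filter_scale)
    cov = np.zeros((FILTER_LENGTH + 1, FILTER_LENGTH + 1))
    cov[0, 0] = bias_sd ** 2
    cov[1:, 1:] = sp.cov
    mean = np.zeros(FILTER_LENGTH + 1)
    mean[0] = bias_mean
    return PriorSpec(kind="gaussian", mean=mean, cov=cov)


def make_temporal_design(T: int = T_BINS, seed: int = 0) -> np.ndarray:
    """T x 9 design matrix: row i holds the white-noise input between time
    bins i-8 and i."""
    rng = np.random.default_rng(seed)
    stim = rng.standard_normal(T + FILTER_LENGTH - 1)
    return np.lib.stride_tricks.sliding_window_view(stim, FILTER_LENGTH)


def simulate_temporal_glm(params: TemporalGlmParams, design: np.ndarray,
                          seed: int = 0) -> np.ndarray:
    """Bernoulli spikes z_i ~ Bern(sigmoid(v_i . f + beta))."""
    design = np.atleast_2d(np.asarray(design, dtype=float))
    p = _sigmoid(design @ params.filt + params.bias)
    rng = np.random.default_rng(seed)
    return (rng.uniform(size=p.size) < p).astype(float)


def sta_summary(spikes: np.ndarray, design: np.ndarray):
    """Spike count and spike-triggered average ``(1/N) V z``.

    Returns ``(N, sta, well_defined)``; with zero spikes the STA is the
    zero vector and ``well_defined`` is False.
    """
    z = np.asarray(spikes, dtype=float).ravel()
    V = np.atleast_2d(np.asarray(design, dtype=float))
    if V.shape[0] != z.size:
        raise ValueError("design rows must match spike bins")
    N = float(z.sum())
    if N == 0:
        return 0.0, np.zeros(V.shape[1]), False
    return N, (V.T @ z) / N, True


def temporal_glm_log_likelihood(theta, spikes, design) -> np.ndarray:
    """Exact Bernoulli log-likelihood of [bias, filter] rows (for MCMC
    reference posteriors)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    z = np.asarray(spikes, dtype=float).ravel()
    V = np.atleast_2d(np.asarray(design, dtype=float))
    u = theta[:, 1:] @ V.T + theta[:, :1]  # (n, T)
    # log Bern(z | sigmoid(u)) = z*u - log(1 + e^u)
    return u @ z - np.logaddexp(0.0, u).sum(axis=1)


def make_temporal_glm_simulator(design: np.ndarray):
    """Batch simulator/extractor pair over theta = [bias, f1..f9]; features
    are [N, STA]."""
    design = np.atleast_2d(np.asarray(design, dtype=float))

    def simulator(theta_batch, row_seeds):
        theta_batch = np.atleast_2d(theta_batch)
        out = []
        for th, s in zip(theta_batch, row_seeds):
            params = TemporalGlmParams(th[1:], th[0])
            out.append(simulate_temporal_glm(params, design, int(s)))
        return out

    simulator.batch = True
    simulator.name = "temporal_glm"

    def extractor(spikes):
        N, sta, _ = sta_summary(spikes, design)
        return np.concatenate([[N], sta])

    extractor.name = "count_and_sta"
    return simulator, extractor


# ---------------------------------------------------------------------------
# Gabor-parameterized Poisson GLM


@dataclass
class GaborParams:
    """Gabor receptive-field parameters (all within open bounds)."""

    gain: float
    freq: float
    aspect: float
    width: float
    phase: float  # in (0, pi)
    angle: float  # in (0, 2 pi)
    x: float      # in (-1, 1)
    y: float      # in (-1, 1)
    bias: float = 0.0

    def __post_init__(self):
        if min(self.gain, self.freq, self.aspect, self.width) <= 0:
            raise ValueError("gain, freq, aspect and width must be positive")
        if not (0 < self.phase < np.pi):
            raise ValueError("phase must lie in (0, pi)")
        if not (0 < self.angle < 2 * np.pi):
            raise ValueError("angle must lie in (0, 2 pi)")
        if not (-1 < self.x < 1 and -1 < self.y < 1):
            raise ValueError("location must lie in (-1, 1)^2")


def gabor_sigma(freq: float, width: float) -> float:
    """Envelope width from spatial frequency and octave bandwidth:
    ``sigma = sqrt(2 ln 2) / (2 pi f) * (2^w + 1) / (2^w - 1)``."""
    return (np.sqrt(2.0 * np.log(2.0)) / (2.0 * np.pi * freq)
            * (2.0 ** width + 1.0) / (2.0 ** width - 1.0))


def gabor_grid(n: int = 41):
    """Regular n x n grid of positions spanning [-1, 1]^2."""
    g = np.linspace(-1.0, 1.0, n)
    return np.meshgrid(g, g, indexing="ij")


def gabor_filter(params: GaborParams, n: int = 41) -> np.ndarray:
    """Evaluate the Gabor receptive field on an n x n grid over [-1,1]^2."""
    gx, gy = gabor_grid(n)
    cx, cy = gx - params.x, gy - params.y
    xp = cx * np.cos(params.angle) - cy * np.sin(params.angle)
    yp = cx * np.sin(params.angle) + cy * np.cos(params.angle)
    sigma = gabor_sigma(params.freq, params.width)
    env = np.exp(-(xp ** 2 + params.aspect ** 2 * yp ** 2) / (2 * sigma ** 2))
    return params.gain * env * np.cos(2 * np.pi * params.freq * xp - params.phase)


_RATE_CAP = 1e6  # spikes per bin beyond which the row is declared invalid


def simulate_gabor_glm(params: GaborParams, movie: np.ndarray,
                       dt: float = 0.025, seed: int = 0) -> np.ndarray:
    """Poisson counts z_i ~ Poiss(exp(v_i . h + beta)) per movie frame.

    Returns NaNs when the rate overflows (row flagged invalid downstream).
    """
    movie = np.asarray(movie, dtype=float)
    n = movie.shape[1]
    h = gabor_filter(params, n).ravel()
    u = movie.reshape(movie.shape[0], -1) @ h + params.bias
    rate = np.exp(np.minimum(u, 700.0))
    if np.any(rate > _RATE_CAP):
        return np.full(movie.shape[0], np.nan)
    rng = np.random.default_rng(seed)
    return rng.poisson(rate).astype(float)


_GABOR_TRANSFORMS = [
    Transform("log"), Transform("log"), Transform("log"), Transform("log"),
    Transform("logit", 0.0, np.pi), Transform("logit", 0.0, 2 * np.pi),
    Transform("logit", -1.0, 1.0), Transform("logit", -1.0, 1.0),
    Transform("identity"),
]


def transform_gabor(params: GaborParams) -> np.ndarray:
    """Map to the unconstrained 9-vector
    [log g, log f, log r, log w, logit phase, logit angle, logit x,
    logit y, bias]."""
    native = np.array([params.gain, params.freq, params.aspect, params.width,
                       params.phase, params.angle, params.x, params.y,
                       params.bias])
    out = np.array([t.forward(v) for t, v in zip(_GABOR_TRANSFORMS, native)])
    if not np.all(np.isfinite(out)):
        raise ValueError("parameters on a bound transform to infinity")
    return out


def untransform_gabor(phi: np.ndarray) -> GaborParams:
    phi = np.asarray(phi, dtype=float).ravel()
    vals = [t.inverse(v) for t, v in zip(_GABOR_TRANSFORMS, phi)]
    return GaborParams(*[float(v) for v in vals])


def gabor_prior() -> PriorSpec:
    """Factorizing Gaussian on the transformed Gabor parameters: zero mean
    with SDs [0.5, 0.5, 0.5, 0.5, 1.9, 1.78, 1.78, 1.78]; bias Gaussian
    with mean -0.57 and variance 1.63 (close to a unit-rate exponential
    prior on the baseline firing rate)."""
    sds = np.array([0.5, 0.5, 0.5, 0.5, 1.9, 1.78, 1.78, 1.78,
                    np.sqrt(1.63)])
    mean = np.zeros(9)
    mean[8] = -0.57
    return PriorSpec(kind="gaussian", mean=mean, cov=np.diag(sds ** 2))
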