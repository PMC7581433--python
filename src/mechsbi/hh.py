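"""Stochastic single-compartment Hodgkin-Huxley neuron.

Membrane equation (densities in mS/cm^2, voltages mV, time ms):

.. math::
    C_m \\dot V = g_l(E_l - V) + \\bar g_{Na} m^3 h (E_{Na} - V)
    + \\bar g_K n^4 (E_K - V) + \\bar g_M p (E_K - V) + I_{inj}
    + \\sigma \\eta(t),

with transient sodium, delayed-rectifier potassium, slow (M-type)
potassium and leak currents, and intrinsic Gaussian voltage noise scaled
by ``1/sqrt(dt)`` so sigma has consistent units across step sizes.  The
gating kinetics (the rate functions for m, h, n and the M-current
activation p) follow the standard cortical-neuron formulation in which a
threshold-shift parameter V_T moves the spike threshold and tau_max
scales the adaptation time constant; they are isolated in
:func:`gating_rates` so alternates can be swapped in.

The eight inferred parameters are ``[gNa, gK, gl, gM, tau_max, VT, sigma,
El]``; V_T and E_l are sampled as positive magnitudes and applied with a
negative sign (their physical values are -VT and -El mV).

Summary features: spike count, mean and SD of the resting potential
(pre-stimulus window), and the first four voltage moments (mean, SD,
skewness, kurtosis) during the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .density import MdnConfig, TrainConfig
from .priors import PriorSpec
from .snpe import run_snpe

__all__ = [
    "HH_PRIOR_LOW",
    "HH_PRIOR_HIGH",
    "hh_prior",
    "HhConstants",
    "StimulusProtocol",
    "gating_rates",
    "simulate_hh",
    "spike_times",
    "hh_features",
    "FEATURE_NAMES",
    "make_hh_simulator",
    "run_hh_inference",
]

# prior box over [gNa, gK, gl, gM, tau_max, VT, sigma, El]
HH_PRIOR_LOW = np.array([0.5, 1e-4, 1e-4, 1e-4, 50.0, 40.0, 1e-4, 35.0])
HH_PRIOR_HIGH = np.array([80.0, 15.0, 0.6, 0.6, 3000.0, 90.0, 0.15, 100.0])

FEATURE_NAMES = ["spike_count", "resting_mean", "resting_sd",
                 "moment_mean", "moment_sd", "moment_skew", "moment_kurt"]


def hh_prior() -> PriorSpec:
    return PriorSpec(kind="uniform", lower=HH_PRIOR_LOW, upper=HH_PRIOR_HIGH)


@dataclass(frozen=True)
class HhConstants:
    C_m: float = 1.0     # uF/cm^2
    E_Na: float = 53.0   # mV
    E_K: float = -107.0  # mV


@dataclass(frozen=True)
class StimulusProtocol:
    """Square depolarizing current pulse inside a recording window."""

    duration: float = 120.0   # ms
    stim_start: float = 10.0  # ms
    stim_end: float = 90.0    # ms
    amplitude: float = 5.0    # uA/cm^2
    dt: float = 0.025         # ms

    def current(self) -> np.ndarray:
        t = np.arange(0.0, self.duration, self.dt)
        return np.where((t >= self.stim_start) & (t < self.stim_end),
                        self.amplitude, 0.0)


def _safe_expm1_ratio(x):
    """x / (exp(x) - 1), continuous at 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-7, 1.0 - x / 2.0, x / np.expm1(np.where(
        np.abs(x) < 1e-7, 1.0, x)))
    return out


def gating_rates(V, VT, tau_max):
    """Steady states and time constants of m, h, n, p at voltage V.

    Replaceable kinetics unit (standard cortical-neuron rate functions);
    V_T shifts the activation curves of m, h, n; tau_max scales the
    adaptation time constant of p.  Returns dict name -> (q_inf, tau_q).
    """
    V = np.asarray(V, dtype=float)
    u = V - VT
    am = 0.32 * 4.0 * _safe_expm1_ratio(-(u - 13.0) / 4.0)
    bm = 0.28 * 5.0 * _safe_expm1_ratio((u - 40.0) / 5.0)
    ah = 0.128 * np.exp(np.clip(-(u - 17.0) / 18.0, -500, 500))
    bh = 4.0 / (1.0 + np.exp(np.clip(-(u - 40.0) / 5.0, -500, 500)))
    an = 0.032 * 5.0 * _safe_expm1_ratio(-(u - 15.0) / 5.0)
    bn = 0.5 * np.exp(np.clip(-(u - 10.0) / 40.0, -500, 500))
    p_inf = 1.0 / (1.0 + np.exp(np.clip(-(V + 35.0) / 10.0, -500, 500)))
    tau_p = tau_max / (3.3 * np.exp(np.clip((V + 35.0) / 20.0, -500, 500))
                       + np.exp(np.clip(-(V + 35.0) / 20.0, -500, 500)))
    out = {}
    for name, (a, b) in {"m": (am, bm), "h": (ah, bh), "n": (an, bn)}.items():
        s = a + b
        out[name] = (a / s, 1.0 / s)
    out["p"] = (p_inf, tau_p)
    return out


def simulate_hh(params, protocol: StimulusProtocol | None = None,
                dt: float | None = None, seed: int = 0,
                constants: HhConstants = HhConstants()) -> np.ndarray:
    """Voltage traces for one or many parameter rows (batch-vectorized).

    Exponential Euler for the gating variables, forward Euler for the
    voltage; per-step noise ``sigma * N(0,1) / sqrt(dt)`` added to dV/dt.
    Rows that blow up numerically are returned as NaN traces.
    """
    protocol = protocol or StimulusProtocol()
    dt = dt if dt is not None else protocol.dt
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms")
    theta = np.atleast_2d(np.asarray(params, dtype=float))
    gNa, gK, gl, gM, tau_max, VT, sigma, El = theta.T
    VT = -VT  # sampled as positive magnitudes of negative quantities
    El = -El
    I_t = np.where(
        (np.arange(0.0, protocol.duration, dt) >= protocol.stim_start)
        & (np.arange(0.0, protocol.duration, dt) < protocol.stim_end),
        protocol.amplitude, 0.0)
    n_steps = I_t.size
    nb = theta.shape[0]
    rng = np.random.default_rng(seed)
    V = El.copy()
    g0 = gating_rates(V, VT, tau_max)
    m, h, n, p = (g0[k][0].copy() for k in ("m", "h", "n", "p"))
    out = np.empty((nb, n_steps))
    noise_scale = sigma / np.sqrt(dt)
    chunk = 1000
    noise = None
    with np.errstate(invalid="ignore", over="ignore"):  # blown-up rows
        for i in range(n_steps):                        # become NaN traces
            if i % chunk == 0:
                noise = rng.standard_normal((min(chunk, n_steps - i), nb))
            I_ion = (gl * (El - V) + gNa * m ** 3 * h * (constants.E_Na - V)
                     + gK * n ** 4 * (constants.E_K - V)
                     + gM * p * (constants.E_K - V))
            dV = (I_ion + I_t[i]
                  + noise_scale * noise[i % chunk]) / constants.C_m
            V = V + dt * dV
            g = gating_rates(V, VT, tau_max)
            m = g["m"][0] + (m - g["m"][0]) * np.exp(-dt / g["m"][1])
            h = g["h"][0] + (h - g["h"][0]) * np.exp(-dt / g["h"][1])
            n = g["n"][0] + (n - g["n"][0]) * np.exp(-dt / g["n"][1])
            p = g["p"][0] + (p - g["p"][0]) * np.exp(-dt / g["p"][1])
            out[:, i] = V
    bad = ~np.all(np.isfinite(out), axis=1)
    out[bad] = np.nan
    return out


def spike_times(trace: np.ndarray, dt: float, threshold: float = -20.0,
                refractory: float = 1.0) -> np.ndarray:
    """Upward threshold crossings with a refractory period (ms)."""
    v = np.asarray(trace, dtype=float)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    if up.size == 0:
        return up.astype(float) * dt
    keep = [up[0]]
    for idx in up[1:]:
        if (idx - keep[-1]) * dt >= refractory:
            keep.append(idx)
    return np.asarray(keep) * dt


def hh_features(trace: np.ndarray, protocol: StimulusProtocol | None = None,
                dt: float | None = None, threshold: float = -20.0,
                feature_sds: np.ndarray | None = None) -> np.ndarray:
    """Seven voltage features: spike count, resting mean and SD
    (pre-stimulus window), and the first four voltage moments during the
    stimulus.  Optionally normalized by prior-predictive SDs."""
    protocol = protocol or StimulusProtocol()
    dt = dt if dt is not None else protocol.dt
    v = np.asarray(trace, dtype=float)
    t = np.arange(v.size) * dt
    rest = v[t < protocol.stim_start]
    stim = v[(t >= protocol.stim_start) & (t < protocol.stim_end)]
    if rest.size < 2 or stim.size < 2:
        raise ValueError("windows must contain at least 2 samples")
    sp = spike_times(stim - 0.0, dt, threshold).size if np.all(
        np.isfinite(stim)) else np.nan
    feats = np.array([
        sp,
        rest.mean(), rest.std(),
        stim.mean(), stim.std(),
        sps.skew(stim), sps.kurtosis(stim),
    ])
    if feature_sds is not None:
        feats = feats / np.asarray(feature_sds, dtype=float)
    return feats


def make_hh_simulator(protocol: StimulusProtocol | None = None,
                      dt: float = 0.025, feature_idx=None):
    """Batch simulator/extractor pair over the 8 HH parameters."""
    protocol = protocol or StimulusProtocol()
    idx = np.arange(7) if feature_idx is None else np.asarray(feature_idx)

    def simulator(theta_batch, row_seeds):
        return simulate_hh(theta_batch, protocol, dt=dt,
                           seed=int(row_seeds[0]))

    simulator.batch = True
    simulator.name = "hodgkin_huxley"

    def extractor(trace):
        return hh_features(trace, protocol, dt=dt)[idx]

    extractor.name = f"voltage_features_{idx.size}"
    return simulator, extractor


def run_hh_inference(x_o, budget: int, rounds: int = 1, feature_idx=None,
                     protocol: StimulusProtocol | None = None, seed: int = 0,
                     estimator_config=None,
                     train_config: TrainConfig | None = None):
    """Posterior over the 8 HH parameters given observed features.

    `feature_idx` selects a subset of the 7 features (e.g. spike count
    alone) to study how added features tighten the posterior.
    """
    if budget < 500:
        raise ValueError("simulation budget below 500 is refused")
    idx = np.arange(7) if feature_idx is None else np.asarray(feature_idx)
    x_o = np.asarray(x_o, dtype=float).ravel()
    if x_o.size == 7 and idx.size < 7:
        x_o = x_o[idx]
    sim, ext = make_hh_simulator(protocol, feature_idx=idx)
    cfg = estimator_config or MdnConfig(n_params=8, n_features=idx.size,
                                        n_components=1, seed=seed)
    return run_snpe(hh_prior(), sim, ext, x_o, rounds=rounds,
                    n_per_round=budget // rounds, estimator_config=cfg,
                    seed=seed, train_config=train_config)
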