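"""Non-inactivating potassium-channel family ("Omnimodel").

An eight-parameter kinetics family subsuming a wide range of published
non-inactivating K+ channel models: a two-parameter Boltzmann steady-state
activation curve and a six-parameter bell-shaped time-constant curve,

.. math::
    m_\\infty(V) = \\frac{1}{1 + e^{-\\theta_1 V + \\theta_2}}, \\qquad
    \\tau_m(V) = \\frac{\\theta_4}
        {e^{-[\\theta_5\\Delta + \\theta_6\\Delta^2]}
         + e^{[\\theta_7\\Delta + \\theta_8\\Delta^2]}}, \\quad
    \\Delta = V - \\theta_3.

Current responses ``I_K = \\bar g_K m (V - E_K)`` to five noisy
voltage-clamp protocols (activation, inactivation ladder, deactivation,
ramp, action potential; 0.5 mV Gaussian noise per sample) are reduced to
55 summary features: per protocol, 10 principal-component coefficients
plus one least-squares linear-offset coefficient.

The five protocol waveforms here are desk-scale stand-ins for the original
database protocols, defined in :func:`default_protocols`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .priors import PriorSpec

__all__ = [
    "OMNIMODEL_PRIOR_LOW",
    "OMNIMODEL_PRIOR_HIGH",
    "omnimodel_prior",
    "steady_state",
    "time_constant",
    "VoltageClampProtocol",
    "default_protocols",
    "simulate_current",
    "simulate_protocols",
    "PcaFeatureBasis",
    "fit_pca_basis",
    "channel_features",
    "make_omnimodel_simulator",
]

E_K = -107.0  # mV, matching the Hodgkin-Huxley module
G_K = 1.0     # normalized out by the max-normalization of responses
NOISE_SD = 0.5  # mV, per-sample Gaussian noise on every clamp command
N_COMPONENTS = 10
N_PROTOCOLS = 5

OMNIMODEL_PRIOR_LOW = np.array([0.0, -10.0, -120.0, 0.0, 0.0, 0.0, 0.0, 0.0])
OMNIMODEL_PRIOR_HIGH = np.array([1.0, 10.0, 120.0, 2000.0, 0.5, 0.05, 0.5, 0.05])


def omnimodel_prior() -> PriorSpec:
    return PriorSpec(kind="uniform", lower=OMNIMODEL_PRIOR_LOW,
                     upper=OMNIMODEL_PRIOR_HIGH)


def steady_state(V, theta1, theta2):
    """Boltzmann steady-state activation 1 / (1 + exp(-theta1 V + theta2))."""
    return 1.0 / (1.0 + np.exp(np.clip(-theta1 * np.asarray(V, dtype=float)
                                       + theta2, -500, 500)))


def time_constant(V, theta3, theta4, theta5, theta6, theta7, theta8):
    """Bell-shaped activation time constant (ms); strictly positive.

    Exponents are clamped at +-60 to avoid overflow at extreme voltages
    (the clamped tau underflows smoothly toward zero there).
    """
    d = np.asarray(V, dtype=float) - theta3
    e1 = np.clip(-(theta5 * d + theta6 * d * d), -60.0, 60.0)
    e2 = np.clip(theta7 * d + theta8 * d * d, -60.0, 60.0)
    return theta4 / (np.exp(e1) + np.exp(e2))


@dataclass
class VoltageClampProtocol:
    """Command-voltage waveform with fixed per-sample noise SD of 0.5 mV."""

    name: str
    waveform: np.ndarray  # command voltage (mV) at each time step
    dt: float  # ms

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float).ravel()
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform must be finite")


def _steps(segments, dt):
    """Concatenate (voltage, duration_ms) segments into a waveform."""
    parts = [np.full(max(int(round(dur / dt)), 1), v) for v, dur in segments]
    return np.concatenate(parts)


def default_protocols(dt: float = 0.025) -> list[VoltageClampProtocol]:
    """Desk-scale stand-ins for the five standard clamp protocols."""
    protos = []
    # activation: holding -80, depolarizing steps -40..+40 mV
    seg = [(-80.0, 10.0)]
    for v in (-40.0, -20.0, 0.0, 20.0, 40.0):
        seg += [(v, 40.0), (-80.0, 10.0)]
    protos.append(VoltageClampProtocol("activation", _steps(seg, dt), dt))
    # "inactivation": holding-potential ladder before a test step
    seg = []
    for v in (-100.0, -80.0, -60.0, -40.0, -20.0):
        seg += [(v, 30.0), (40.0, 20.0)]
    protos.append(VoltageClampProtocol("inactivation", _steps(seg, dt), dt))
    # deactivation: step to +40 then repolarizing steps
    seg = [(-80.0, 10.0), (40.0, 30.0)]
    for v in (-120.0, -100.0, -80.0, -60.0, -40.0):
        seg += [(v, 30.0)]
    protos.append(VoltageClampProtocol("deactivation", _steps(seg, dt), dt))
    # ramp: linear -80 -> +40 mV
    n = int(round(150.0 / dt))
    protos.append(VoltageClampProtocol(
        "ramp", np.linspace(-80.0, 40.0, n), dt))
    # action potential: stereotyped spike waveform template
    t = np.arange(0.0, 150.0, dt)
    ap = -70.0 + 100.0 * np.exp(-0.5 * ((t - 40.0) / 1.2) ** 2) \
        - 12.0 * np.exp(-0.5 * ((t - 48.0) / 6.0) ** 2)
    protos.append(VoltageClampProtocol("action-potential", ap, dt))
    return protos


def simulate_current(params, protocol: VoltageClampProtocol,
                     dt: float | None = None, seed: int = 0,
                     record_stride: int = 1,
                     noise_sd: float = NOISE_SD) -> np.ndarray:
    """Max-normalized K+ current of one or many parameter rows under the
    clamped noisy waveform.

    The gating ODE ``dm/dt = (m_inf(V) - m)/tau_m(V)`` is integrated by
    exponential Euler (exact for piecewise-constant V).  Returns an array
    of shape (n_rows, n_recorded).
    """
    theta = np.atleast_2d(np.asarray(params, dtype=float))
    dt = dt if dt is not None else protocol.dt
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 ms")
    stride = max(int(round(dt / protocol.dt)), 1)
    command = protocol.waveform[::stride]
    rng = np.random.default_rng(seed)
    n = theta.shape[0]
    V = command[None, :] + (rng.normal(0.0, noise_sd, size=(n, command.size))
                            if noise_sd > 0 else 0.0)
    th = theta.T
    m = steady_state(V[:, 0], th[0], th[1])
    n_rec = (command.size + record_stride - 1) // record_stride
    out = np.empty((n, n_rec))
    j = 0
    for i in range(command.size):
        Vi = V[:, i]
        minf = steady_state(Vi, th[0], th[1])
        tau = time_constant(Vi, th[2], th[3], th[4], th[5], th[6], th[7])
        m = minf + (m - minf) * np.exp(-dt / np.maximum(tau, 1e-12))
        if i % record_stride == 0:
            out[:, j] = G_K * m * (Vi - E_K)
            j += 1
    peak = np.max(np.abs(out), axis=1, keepdims=True)
    peak[peak == 0.0] = 1.0  # zero driving force: leave the zero trace as is
    out = out / peak
    out[~np.all(np.isfinite(out), axis=1)] = np.nan
    return out


def simulate_protocols(params, protocols=None, dt: float = 0.1, seed: int = 0,
                       record_stride: int = 5,
                       noise_sd: float = NOISE_SD) -> list[np.ndarray]:
    """Responses to all five protocols; list of (n_rows, n_rec) arrays."""
    protocols = protocols or default_protocols(dt)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(protocols))
    return [simulate_current(params, p, dt=max(dt, p.dt), seed=int(s),
                             record_stride=record_stride, noise_sd=noise_sd)
            for p, s in zip(protocols, seeds)]


@dataclass
class PcaFeatureBasis:
    """Per-protocol orthonormal PCA loadings plus the training means;
    the 55-feature map is 10 projection coefficients + 1 offset per
    protocol."""

    components: list  # per protocol: (10, L) orthonormal rows
    means: list  # per protocol: (L,) training mean trace
    explained_variance_ratio: list
    provenance: str = "prior-predictive simulations"

    @property
    def n_features(self) -> int:
        return len(self.components) * (N_COMPONENTS + 1)


def fit_pca_basis(training_traces: list[np.ndarray],
                  provenance: str = "prior-predictive simulations"
                  ) -> PcaFeatureBasis:
    """Fit the per-protocol PCA loadings from >= 50 training responses."""
    comps, means, evr = [], [], []
    for traces in training_traces:
        X = np.atleast_2d(traces)
        X = X[np.all(np.isfinite(X), axis=1)]
        if X.shape[0] < 50:
            raise ValueError("need >= 50 valid training simulations per protocol")
        pca = PCA(n_components=N_COMPONENTS)
        pca.fit(X)
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < N_COMPONENTS:
            raise ValueError("rank-deficient training matrix")
        comps.append(pca.components_)
        means.append(pca.mean_)
        evr.append(pca.explained_variance_ratio_)
    return PcaFeatureBasis(comps, means, evr, provenance)


def channel_features(traces: list[np.ndarray], basis: PcaFeatureBasis
                     ) -> np.ndarray:
    """Reduce per-protocol traces to the concatenated 55-vector.

    Per protocol: 10 PCA projection coefficients of the mean-centered
    trace, plus the least-squares coefficient on the constant regressor
    (the trace mean).
    """
    rows = None
    feats = []
    for traces_p, comp, mean in zip(traces, basis.components, basis.means):
        X = np.atleast_2d(traces_p)
        rows = X.shape[0] if rows is None else rows
        offset = X.mean(axis=1, keepdims=True)
        coef = (X - mean) @ comp.T
        feats.append(np.hstack([coef, offset]))
    return np.hstack(feats)


def make_omnimodel_simulator(basis: PcaFeatureBasis, protocols=None,
                             dt: float = 0.1, record_stride: int = 5):
    """Batch simulator/extractor pair for the SNPE loop: raw output is the
    list of per-protocol traces for the whole batch."""

    def simulator(theta_batch, row_seeds):
        traces = simulate_protocols(theta_batch, protocols, dt=dt,
                                    seed=int(row_seeds[0]),
                                    record_stride=record_stride)
        n = np.atleast_2d(theta_batch).shape[0]
        return [[tr[i] for tr in traces] for i in range(n)]

    simulator.batch = True
    simulator.name = "omnimodel"

    def extractor(row_traces):
        return channel_features([t[None, :] for t in row_traces], basis)[0]

    extractor.name = "pca_features_55"
    return simulator, extractor
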