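"""Three-neuron pyloric circuit of the crustacean stomatogastric ganglion.

Single-compartment AB/PD, LP and PY neurons, each with eight membrane
currents (Na, CaT, CaS, A, KCa, Kd, H, leak) following the published
pyloric-network formulation (Prinz-type kinetics, isolated in
:func:`membrane_gates` as a replaceable unit, with intracellular calcium
dynamics driving the KCa current and a Nernstian calcium reversal), and
seven graded inhibitory synapses

.. math::
    I_s = g_s\\, s\\, (V_{post} - E_s), \\qquad
    \\dot s = (\\bar s(V_{pre}) - s)/\\tau_s,

with :math:`\\bar s(V_{pre}) = 1/(1+\\exp((V_{th}-V_{pre})/\\delta))` and
:math:`\\tau_s = (1-\\bar s(V_{pre}))/k_-`.  Glutamatergic synapses (from
AB, LP, PY) have E_s = -70 mV and k_- = 1/40 ms; cholinergic synapses
(from PD) have E_s = -80 mV and k_- = 1/100 ms; V_th = -35 mV, delta = 5 mV.

Parameters: 24 maximal membrane conductances (3 neurons x 8 currents,
mS/cm^2) followed by 7 maximal synaptic conductances handled in log10
space (nS).  Each neuron receives per-step Gaussian voltage noise with
SD 0.001 mV.ms^-0.5 (scaled by sqrt(dt)).

Summary features: 15 pyloric-rhythm features (cycle period, burst
durations, gaps, delays, duty cycles, phase gaps, start phases) that are
only defined when every neuron bursts rhythmically, plus 3 plateau
features (maximal time above -30 mV, floored at 5 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import PriorSpec

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "STG_PRIOR_LOW",
    "STG_PRIOR_HIGH",
    "stg_prior",
    "SynapseConfig",
    "SYNAPSES",
    "synapse_state",
    "synaptic_current",
    "membrane_gates",
    "simulate_stg",
    "pyloric_features",
    "PyloricFeatures",
    "FEATURE_NAMES",
    "make_stg_simulator",
]

# membrane conductance boxes, currents ordered [Na, CaT, CaS, A, KCa, Kd, H, leak]
_AB_LOW = [0.0, 0.0, 0.0, 0.0, 0.0, 25.0, 0.0, 0.0]
_AB_HIGH = [500.0, 7.5, 8.0, 60.0, 15.0, 150.0, 0.2, 0.01]
_LP_LOW = [0.0, 0.0, 2.0, 10.0, 0.0, 0.0, 0.0, 0.01]
_LP_HIGH = [200.0, 2.5, 12.0, 60.0, 10.0, 125.0, 0.06, 0.04]
_PY_LOW = [0.0, 0.0, 0.0, 30.0, 0.0, 50.0, 0.0, 0.0]
_PY_HIGH = [600.0, 12.5, 4.0, 60.0, 5.0, 150.0, 0.06, 0.04]

# synaptic conductances log10-uniform in [0.01, 1000] nS (AB->LP: up to 10^4)
_SYN_LOW = [-2.0, -2.0, -2.0, -2.0, -2.0, -2.0, -2.0]
_SYN_HIGH = [4.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0]

STG_PRIOR_LOW = np.array(_AB_LOW + _LP_LOW + _PY_LOW + _SYN_LOW)
STG_PRIOR_HIGH = np.array(_AB_HIGH + _LP_HIGH + _PY_HIGH + _SYN_HIGH)

MEMBRANE_AREA = 0.628e-3  # cm^2
C_M = 1.0  # uF/cm^2
NOISE_SD = 0.001  # mV * ms^-0.5
E_LEAK = -50.0
E_K = -80.0
E_H = -20.0
E_NA = 50.0
CA_OUT = 3000.0  # uM extracellular calcium
TAU_CA = 200.0  # ms
CA_FACTOR = 14.96  # uM/nA
CA_REST = 0.05  # uM
RTzF = 12.199  # mV (RT/2F at ~10 degrees C)

FEATURE_NAMES = [
    "period", "burst_dur_AB", "burst_dur_LP", "burst_dur_PY",
    "gap_ABend_LPstart", "gap_LPend_PYstart",
    "delay_ABstart_LPstart", "delay_LPstart_PYstart",
    "duty_AB", "duty_LP", "duty_PY",
    "phase_gap_AB_LP", "phase_gap_LP_PY", "phase_LP", "phase_PY",
    "plateau_AB", "plateau_LP", "plateau_PY",
]


def stg_prior() -> PriorSpec:
    """Uniform box over the 31-vector (synapses in log10 nS)."""
    return PriorSpec(kind="uniform", lower=STG_PRIOR_LOW, upper=STG_PRIOR_HIGH)


@dataclass(frozen=True)
class SynapseConfig:
    """Reversal and dissociation constants per transmitter type."""

    E_s: float
    k_minus: float  # 1/ms
    V_th: float = -35.0
    delta: float = 5.0


GLUTAMATERGIC = SynapseConfig(E_s=-70.0, k_minus=1.0 / 40.0)
CHOLINERGIC = SynapseConfig(E_s=-80.0, k_minus=1.0 / 100.0)

# (presynaptic neuron index, postsynaptic neuron index, config);
# AB/PD=0, LP=1, PY=2.  AB, LP, PY are glutamatergic; PD is cholinergic.
SYNAPSES = [
    ("AB-LP", 0, 1, GLUTAMATERGIC),
    ("PD-LP", 0, 1, CHOLINERGIC),
    ("AB-PY", 0, 2, GLUTAMATERGIC),
    ("PD-PY", 0, 2, CHOLINERGIC),
    ("LP-PD", 1, 0, GLUTAMATERGIC),
    ("LP-PY", 1, 2, GLUTAMATERGIC),
    ("PY-LP", 2, 1, GLUTAMATERGIC),
]


def synapse_state(V_pre, config: SynapseConfig):
    """Steady-state activation and time constant of a graded synapse."""
    s_bar = 1.0 / (1.0 + np.exp((config.V_th - np.asarray(V_pre, dtype=float))
                                / config.delta))
    tau_s = (1.0 - s_bar) / config.k_minus
    return s_bar, tau_s


def synaptic_current(g_s, s, V_post, E_s):
    """I_s = g_s * s * (V_post - E_s)."""
    return g_s * s * (np.asarray(V_post, dtype=float) - E_s)


def _boltz(V, vh, k):
    return 1.0 / (1.0 + np.exp((V + vh) / k))


def membrane_gates(V, Ca):
    """Steady states and time constants of the 12 gating variables.

    Returns ``{current: (m_inf, tau_m[, h_inf, tau_h])}`` following the
    published pyloric-model kinetics; the KCa activation depends on the
    intracellular calcium concentration (uM).
    """
    V = np.asarray(V, dtype=float)
    g = {}
    g["Na"] = (
        _boltz(V, 25.5, -5.29),
        1.32 - 1.26 / (1.0 + np.exp((V + 120.0) / -25.0)),
        _boltz(V, 48.9, 5.18),
        (0.67 / (1.0 + np.exp((V + 62.9) / -10.0)))
        * (1.5 + 1.0 / (1.0 + np.exp((V + 34.9) / 3.6))),
    )
    g["CaT"] = (
        _boltz(V, 27.1, -7.2),
        43.4 - 42.6 / (1.0 + np.exp((V + 68.1) / -20.5)),
        _boltz(V, 32.1, 5.5),
        210.0 - 179.6 / (1.0 + np.exp((V + 55.0) / -16.9)),
    )
    g["CaS"] = (
        _boltz(V, 33.0, -8.1),
        2.8 + 14.0 / (np.exp((V + 27.0) / 10.0) + np.exp((V + 70.0) / -13.0)),
        _boltz(V, 60.0, 6.2),
        120.0 + 300.0 / (np.exp((V + 55.0) / 9.0) + np.exp((V + 65.0) / -16.0)),
    )
    g["A"] = (
        _boltz(V, 27.2, -8.7),
        23.2 - 20.8 / (1.0 + np.exp((V + 32.9) / -15.2)),
        _boltz(V, 56.9, 4.9),
        77.2 - 58.4 / (1.0 + np.exp((V + 38.9) / -26.5)),
    )
    g["KCa"] = (
        (Ca / (Ca + 3.0)) * _boltz(V, 28.3, -12.6),
        180.6 - 150.2 / (1.0 + np.exp((V + 46.0) / -22.7)),
    )
    g["Kd"] = (
        _boltz(V, 12.3, -11.8),
        14.4 - 12.8 / (1.0 + np.exp((V + 28.3) / -19.2)),
    )
    g["H"] = (
        _boltz(V, 75.0, 5.5),
        2.0 / (np.exp((V + 169.7) / -11.6) + np.exp((V - 26.7) / 14.3)),
    )
    return g


_CURRENTS = ["Na", "CaT", "CaS", "A", "KCa", "Kd", "H"]
_EXPONENTS = {"Na": 3, "CaT": 3, "CaS": 3, "A": 3, "KCa": 4, "Kd": 4, "H": 1}
_HAS_H = {"Na", "CaT", "CaS", "A"}


@_njit(cache=False)
def _stg_kernel(V, Ca, m, h, s, gmem, gsyn, syn_pre, syn_post, syn_E, syn_k,
                noise, noise_amp, dt, stride, out, step0):
    """Compiled inner loop over one chunk of time steps.

    Scalar math mirrors :func:`membrane_gates` and :func:`synapse_state`;
    state arrays are updated in place, recorded every `stride` steps.
    """
    nb = V.shape[1]
    nsyn = gsyn.shape[1]
    n_rec = out.shape[2]
    for t in range(noise.shape[0]):
        gstep = step0 + t
        rec = gstep // stride
        do_rec = (gstep % stride == 0) and (rec < n_rec)
        for b in range(nb):
            i0 = 0.0
            i1 = 0.0
            i2 = 0.0
            for j in range(nsyn):
                post = syn_post[j]
                cur = gsyn[b, j] * s[j, b] * (V[post, b] - syn_E[j])
                if post == 0:
                    i0 += cur
                elif post == 1:
                    i1 += cur
                else:
                    i2 += cur
            for k in range(3):
                v = V[k, b]
                ca = Ca[k, b]
                isyn = i0 if k == 0 else (i1 if k == 1 else i2)
                eca = 12.199 * np.log(3000.0 / max(ca, 1e-6))
                # Na
                minf = 1.0 / (1.0 + np.exp((v + 25.5) / -5.29))
                taum = 1.32 - 1.26 / (1.0 + np.exp((v + 120.0) / -25.0))
                hinf = 1.0 / (1.0 + np.exp((v + 48.9) / 5.18))
                tauh = (0.67 / (1.0 + np.exp((v + 62.9) / -10.0))) \
                    * (1.5 + 1.0 / (1.0 + np.exp((v + 34.9) / 3.6)))
                m[k, 0, b] = minf + (m[k, 0, b] - minf) * np.exp(-dt / taum)
                h[k, 0, b] = hinf + (h[k, 0, b] - hinf) * np.exp(-dt / tauh)
                mm = m[k, 0, b]
                I_Na = gmem[b, k, 0] * mm * mm * mm * h[k, 0, b] * (v - 50.0)
                # CaT
                minf = 1.0 / (1.0 + np.exp((v + 27.1) / -7.2))
                taum = 43.4 - 42.6 / (1.0 + np.exp((v + 68.1) / -20.5))
                hinf = 1.0 / (1.0 + np.exp((v + 32.1) / 5.5))
                tauh = 210.0 - 179.6 / (1.0 + np.exp((v + 55.0) / -16.9))
                m[k, 1, b] = minf + (m[k, 1, b] - minf) * np.exp(-dt / taum)
                h[k, 1, b] = hinf + (h[k, 1, b] - hinf) * np.exp(-dt / tauh)
                mm = m[k, 1, b]
                I_CaT = gmem[b, k, 1] * mm * mm * mm * h[k, 1, b] * (v - eca)
                # CaS
                minf = 1.0 / (1.0 + np.exp((v + 33.0) / -8.1))
                taum = 2.8 + 14.0 / (np.exp((v + 27.0) / 10.0)
                                     + np.exp((v + 70.0) / -13.0))
                hinf = 1.0 / (1.0 + np.exp((v + 60.0) / 6.2))
                tauh = 120.0 + 300.0 / (np.exp((v + 55.0) / 9.0)
                                        + np.exp((v + 65.0) / -16.0))
                m[k, 2, b] = minf + (m[k, 2, b] - minf) * np.exp(-dt / taum)
                h[k, 2, b] = hinf + (h[k, 2, b] - hinf) * np.exp(-dt / tauh)
                mm = m[k, 2, b]
                I_CaS = gmem[b, k, 2] * mm * mm * mm * h[k, 2, b] * (v - eca)
                # A
                minf = 1.0 / (1.0 + np.exp((v + 27.2) / -8.7))
                taum = 23.2 - 20.8 / (1.0 + np.exp((v + 32.9) / -15.2))
                hinf = 1.0 / (1.0 + np.exp((v + 56.9) / 4.9))
                tauh = 77.2 - 58.4 / (1.0 + np.exp((v + 38.9) / -26.5))
                m[k, 3, b] = minf + (m[k, 3, b] - minf) * np.exp(-dt / taum)
                h[k, 3, b] = hinf + (h[k, 3, b] - hinf) * np.exp(-dt / tauh)
                mm = m[k, 3, b]
                I_A = gmem[b, k, 3] * mm * mm * mm * h[k, 3, b] * (v + 80.0)
                # KCa
                minf = (ca / (ca + 3.0)) / (1.0 + np.exp((v + 28.3) / -12.6))
                taum = 180.6 - 150.2 / (1.0 + np.exp((v + 46.0) / -22.7))
                m[k, 4, b] = minf + (m[k, 4, b] - minf) * np.exp(-dt / taum)
                mm = m[k, 4, b]
                I_KCa = gmem[b, k, 4] * mm * mm * mm * mm * (v + 80.0)
                # Kd
                minf = 1.0 / (1.0 + np.exp((v + 12.3) / -11.8))
                taum = 14.4 - 12.8 / (1.0 + np.exp((v + 28.3) / -19.2))
                m[k, 5, b] = minf + (m[k, 5, b] - minf) * np.exp(-dt / taum)
                mm = m[k, 5, b]
                I_Kd = gmem[b, k, 5] * mm * mm * mm * mm * (v + 80.0)
                # H
                minf = 1.0 / (1.0 + np.exp((v + 75.0) / 5.5))
                taum = 2.0 / (np.exp((v + 169.7) / -11.6)
                              + np.exp((v - 26.7) / 14.3))
                m[k, 6, b] = minf + (m[k, 6, b] - minf) * np.exp(-dt / taum)
                I_H = gmem[b, k, 6] * m[k, 6, b] * (v + 20.0)
                I_leak = gmem[b, k, 7] * (v + 50.0)
                I_Ca_tot = I_CaT + I_CaS
                I_mem = I_Na + I_CaT + I_CaS + I_A + I_KCa + I_Kd + I_H + I_leak
                ca_target = 0.05 - 14.96 * (I_Ca_tot * 0.628e-3 * 1e3)
                Ca[k, b] = ca_target + (ca - ca_target) * np.exp(-dt / 200.0)
                vnew = v + dt * (-(I_mem + isyn)) \
                    + noise_amp * noise[t, k, b]
                V[k, b] = vnew
            for j in range(nsyn):
                vpre = V[syn_pre[j], b]
                sbar = 1.0 / (1.0 + np.exp((-35.0 - vpre) / 5.0))
                tau_s = (1.0 - sbar) / syn_k[j]
                if tau_s < 1e-9:
                    tau_s = 1e-9
                s[j, b] = sbar + (s[j, b] - sbar) * np.exp(-dt / tau_s)
            if do_rec:
                for k in range(3):
                    out[b, k, rec] = V[k, b]


def simulate_stg(params, duration: float = 3.0, dt: float = 0.025,
                 seed: int = 0, record_dt: float = 0.25,
                 with_noise: bool = True) -> np.ndarray:
    """Simulate the circuit; returns voltages of shape (n_rows, 3, n_rec).

    `duration` in seconds (desk default 3 s; at least 2 s recommended for
    feature extraction), `dt` and `record_dt` in ms.  The three per-neuron
    noise streams derive from independent substreams of `seed`, so a
    simulation with all synaptic conductances zero reproduces isolated
    single-neuron traces exactly.
    """
    if duration < 0.1:
        raise ValueError("duration too short")
    theta = np.atleast_2d(np.asarray(params, dtype=float))
    nb = theta.shape[0]
    gmem = np.ascontiguousarray(theta[:, :24].reshape(nb, 3, 8))
    gsyn_nS = 10.0 ** theta[:, 24:31]
    # nS -> uA/cm^2 per (mV driving force): g[uS] * dV[mV] = nA; / area -> uA/cm^2
    gsyn = np.ascontiguousarray(gsyn_nS * 1e-3 * 1e-3 / MEMBRANE_AREA)

    n_steps = int(round(duration * 1000.0 / dt))
    stride = max(int(round(record_dt / dt)), 1)
    n_rec = n_steps // stride
    out = np.empty((nb, 3, n_rec))

    ss = np.random.SeedSequence(seed)
    neuron_rngs = [np.random.default_rng(s) for s in ss.spawn(3)]

    V = np.full((3, nb), -65.0)
    Ca = np.full((3, nb), CA_REST)
    m = np.empty((3, 7, nb))
    h = np.empty((3, 4, nb))
    for k in range(3):
        g0 = membrane_gates(V[k], Ca[k])
        for ci, c in enumerate(_CURRENTS):
            m[k, ci] = g0[c][0]
            if c in _HAS_H:
                h[k, ci] = g0[c][2]
    s_syn = np.empty((len(SYNAPSES), nb))
    for j, (_, pre, _post, cfg) in enumerate(SYNAPSES):
        s_syn[j], _ = synapse_state(V[pre], cfg)
    syn_pre = np.array([sy[1] for sy in SYNAPSES], dtype=np.int64)
    syn_post = np.array([sy[2] for sy in SYNAPSES], dtype=np.int64)
    syn_E = np.array([sy[3].E_s for sy in SYNAPSES])
    syn_k = np.array([sy[3].k_minus for sy in SYNAPSES])

    noise_amp = NOISE_SD * np.sqrt(dt) if with_noise else 0.0
    chunk = 4000
    step = _stg_kernel if _HAVE_NUMBA else _stg_chunk_numpy
    for i0 in range(0, n_steps, chunk):
        n_sub = min(chunk, n_steps - i0)
        if with_noise:
            noise = np.stack([r.standard_normal((n_sub, nb))
                              for r in neuron_rngs], axis=1)
        else:
            noise = np.zeros((n_sub, 3, nb))
        step(V, Ca, m, h, s_syn, gmem, gsyn, syn_pre, syn_post, syn_E, syn_k,
             noise, noise_amp, dt, stride, out, i0)
    bad = ~np.all(np.isfinite(out.reshape(nb, -1)), axis=1)
    out[bad] = np.nan
    return out


def _stg_chunk_numpy(V, Ca, m, h, s_syn, gmem, gsyn, syn_pre, syn_post,
                     syn_E, syn_k, noise, noise_amp, dt, stride, out, step0):
    """Vectorized fallback with the same semantics as the compiled kernel."""
    nb = V.shape[1]
    n_rec = out.shape[2]
    for t in range(noise.shape[0]):
        gstep = step0 + t
        I_syn = np.zeros((3, nb))
        for j in range(len(syn_pre)):
            I_syn[syn_post[j]] += gsyn[:, j] * s_syn[j] * (V[syn_post[j]]
                                                           - syn_E[j])
        for k in range(3):
            Vk, Cak = V[k], Ca[k]
            gk = membrane_gates(Vk, Cak)
            E_Ca = RTzF * np.log(CA_OUT / np.maximum(Cak, 1e-6))
            I_mem = np.zeros(nb)
            I_Ca = np.zeros(nb)
            for ci, c in enumerate(_CURRENTS):
                minf, taum = gk[c][0], gk[c][1]
                m[k, ci] = minf + (m[k, ci] - minf) * np.exp(-dt / taum)
                act = m[k, ci] ** _EXPONENTS[c]
                if c in _HAS_H:
                    hinf, tauh = gk[c][2], gk[c][3]
                    h[k, ci] = hinf + (h[k, ci] - hinf) * np.exp(-dt / tauh)
                    act = act * h[k, ci]
                E_c = (E_Ca if c in ("CaT", "CaS")
                       else E_NA if c == "Na"
                       else E_H if c == "H" else E_K)
                I_c = gmem[:, k, ci] * act * (Vk - E_c)
                I_mem += I_c
                if c in ("CaT", "CaS"):
                    I_Ca += I_c
            I_mem += gmem[:, k, 7] * (Vk - E_LEAK)
            Ca_target = CA_REST - CA_FACTOR * (I_Ca * MEMBRANE_AREA * 1e3)
            Ca[k] = Ca_target + (Cak - Ca_target) * np.exp(-dt / TAU_CA)
            V[k] = Vk + dt * (-(I_mem + I_syn[k]) / C_M) \
                + noise_amp * noise[t, k]
        for j in range(len(syn_pre)):
            sbar = 1.0 / (1.0 + np.exp((-35.0 - V[syn_pre[j]]) / 5.0))
            tau_s = np.maximum((1.0 - sbar) / syn_k[j], 1e-9)
            s_syn[j] = sbar + (s_syn[j] - sbar) * np.exp(-dt / tau_s)
        rec = gstep // stride
        if gstep % stride == 0 and rec < n_rec:
            out[:, :, rec] = V.T


# ---------------------------------------------------------------------------
# feature extraction


@dataclass
class PyloricFeatures:
    values: np.ndarray  # length 18, NaN for undefined rhythm features
    valid: bool  # True when all neurons burst rhythmically

    def as_dict(self):
        return dict(zip(FEATURE_NAMES, self.values))


def _local_maxima_spikes(v, dt, threshold):
    """Spike times (s) as local maxima above a voltage threshold."""
    core = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > threshold)
    idx = np.flatnonzero(core) + 1
    if idx.size > 1:  # merge maxima closer than 2 ms (one spike's plateau)
        keep = [idx[0]]
        for i in idx[1:]:
            if (i - keep[-1]) * dt >= 2.0:
                keep.append(i)
        idx = np.asarray(keep)
    return idx * dt / 1000.0


def _segment_bursts(spikes_s):
    """Two-threshold gap classifier: inter-burst gaps are ISIs exceeding
    half the mean inter-burst interval (found by fixed-point iteration);
    a burst needs at least 2 spikes."""
    if spikes_s.size < 4:
        return []
    isi = np.diff(spikes_s)
    if isi.max() < 2.0 * isi.min():  # tonic spiking: no gap structure
        return []
    mask = isi > isi.mean()
    for _ in range(50):
        if not np.any(mask):
            return []
        thr = 0.5 * isi[mask].mean()
        new = isi > thr
        if np.array_equal(new, mask):
            break
        mask = new
    breaks = np.flatnonzero(mask)
    groups = np.split(np.arange(spikes_s.size), breaks + 1)
    bursts = [(spikes_s[g[0]], spikes_s[g[-1]]) for g in groups if g.size >= 2]
    return bursts


def _max_run(mask, dt_ms):
    """Longest run of True, in seconds."""
    if not np.any(mask):
        return 0.0
    d = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    return float(np.max(ends - starts) * dt_ms / 1000.0)


def pyloric_features(traces, record_dt: float = 0.25, transient: float = 1.0,
                     spike_threshold: float = -20.0,
                     plateau_threshold: float = -30.0) -> PyloricFeatures:
    """Extract the 18 summary features from (3, T) voltage traces.

    `record_dt` in ms, `transient` (discarded initial span) in seconds.
    The 15 rhythm features are NaN (and `valid` False) unless every
    neuron shows at least two bursts; the 3 plateau features are always
    computed and floored at 5 ms.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] != 3:
        raise ValueError("expected traces of shape (3, T)")
    n_cut = int(round(transient * 1000.0 / record_dt))
    v = traces[:, n_cut:]
    if v.shape[1] < 2:
        raise ValueError("trace shorter than the discarded transient")
    plateaus = np.maximum(
        [_max_run(v[k] > plateau_threshold, record_dt) for k in range(3)],
        0.005)
    vals = np.full(18, np.nan)
    vals[15:] = plateaus
    if not np.all(np.isfinite(v)):
        return PyloricFeatures(vals, False)
    bursts = []
    for k in range(3):
        sp = _local_maxima_spikes(v[k], record_dt, spike_threshold)
        b = _segment_bursts(sp)
        if len(b) < 2:
            return PyloricFeatures(vals, False)
        bursts.append(b)
    ab, lp, py = bursts
    ab_starts = np.array([b[0] for b in ab])
    T = float(np.mean(np.diff(ab_starts)))
    dur = [float(np.mean([b[1] - b[0] for b in bb])) for bb in bursts]

    def cycle_stats(ref_bursts, other_bursts):
        """Mean (gap from ref end, delay from ref start) to the first
        `other` burst starting within each reference cycle."""
        gaps, delays, other_ends = [], [], []
        starts = [b[0] for b in other_bursts]
        for (s0, e0), s1 in zip(ref_bursts[:-1], ref_bursts[1:]):
            cand = [i for i, t in enumerate(starts) if s0 <= t < s1[0]]
            if not cand:
                continue
            i = cand[0]
            gaps.append(starts[i] - e0)
            delays.append(starts[i] - s0)
            other_ends.append(other_bursts[i][1])
        if not gaps:
            return None
        return float(np.mean(gaps)), float(np.mean(delays))

    ab_lp = cycle_stats(ab, lp)
    if ab_lp is None:
        return PyloricFeatures(vals, False)
    lp_py = cycle_stats(lp, py)
    ab_py = cycle_stats(ab, py)
    if lp_py is None or ab_py is None:
        return PyloricFeatures(vals, False)
    gap_ab_lp, delay_ab_lp = ab_lp
    gap_lp_py, delay_lp_py = lp_py
    _, delay_ab_py = ab_py
    duty = [d / T for d in dur]
    vals[:15] = [T, dur[0], dur[1], dur[2], gap_ab_lp, gap_lp_py,
                 delay_ab_lp, delay_lp_py, duty[0], duty[1], duty[2],
                 gap_ab_lp / T, gap_lp_py / T, delay_ab_lp / T,
                 delay_ab_py / T]
    return PyloricFeatures(vals, True)


def make_stg_simulator(duration: float = 3.0, dt: float = 0.025,
                       record_dt: float = 0.25, transient: float = 1.0,
                       chunk_size: int = 250):
    """Batch simulator/extractor pair over the 31-vector.

    Simulates in chunks to bound memory; rows without a well-defined
    pyloric rhythm yield NaN rhythm features and are flagged invalid by
    the simulation-table machinery.
    """

    def simulator(theta_batch, row_seeds):
        theta_batch = np.atleast_2d(theta_batch)
        out = []
        for i0 in range(0, theta_batch.shape[0], chunk_size):
            tr = simulate_stg(theta_batch[i0:i0 + chunk_size], duration, dt,
                              seed=int(row_seeds[i0]), record_dt=record_dt)
            out.extend(tr)
        return out

    simulator.batch = True
    simulator.name = "stg_circuit"

    def extractor(traces):
        return pyloric_features(traces, record_dt, transient).values

    extractor.name = "pyloric_features_18"
    return simulator, extractor
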