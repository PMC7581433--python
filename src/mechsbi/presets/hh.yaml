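# Stochastic single-compartment Hodgkin-Huxley neuron
model: hh
parameters: [gNa, gK, gl, gM, tau_max, VT, sigma, El]
prior:
  kind: uniform
  lower: [0.5, 1.0e-4, 1.0e-4, 1.0e-4, 50.0, 40.0, 1.0e-4, 35.0]
  upper: [80.0, 15.0, 0.6, 0.6, 3000.0, 90.0, 0.15, 100.0]
protocol:
  duration_ms: 120.0
  stim_start_ms: 10.0
  stim_end_ms: 90.0
  amplitude_uA_cm2: 5.0
  dt_ms: 0.025
features: [spike_count, resting_mean, resting_sd, moment_mean, moment_sd, moment_skew, moment_kurt]
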