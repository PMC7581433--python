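# Three-neuron pyloric circuit (AB/PD, LP, PY); synapses in log10 nS
model: stg
parameters_membrane_order: [Na, CaT, CaS, A, KCa, Kd, H, leak]
synapse_order: [AB-LP, PD-LP, AB-PY, PD-PY, LP-PD, LP-PY, PY-LP]
prior:
  kind: uniform
  lower: [0, 0, 0, 0, 0, 25, 0, 0,
          0, 0, 2, 10, 0, 0, 0, 0.01,
          0, 0, 0, 30, 0, 50, 0, 0,
          -2, -2, -2, -2, -2, -2, -2]
  upper: [500, 7.5, 8, 60, 15, 150, 0.2, 0.01,
          200, 2.5, 12, 60, 10, 125, 0.06, 0.04,
          600, 12.5, 4, 60, 5, 150, 0.06, 0.04,
          4, 3, 3, 3, 3, 3, 3]
simulation:
  duration_s: 3.0
  dt_ms: 0.025
  record_dt_ms: 0.25
  transient_s: 1.0
  noise_sd: 0.001   # mV * ms^-0.5
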