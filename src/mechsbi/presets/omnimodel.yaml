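# Non-inactivating K+ channel family (8 kinetics parameters)
model: omnimodel
parameters: [theta1, theta2, theta3, theta4, theta5, theta6, theta7, theta8]
prior:
  kind: uniform
  lower: [0.0, -10.0, -120.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  upper: [1.0, 10.0, 120.0, 2000.0, 0.5, 0.05, 0.5, 0.05]
protocols: [activation, inactivation, deactivation, ramp, action-potential]
noise_sd_mV: 0.5
features_per_protocol: 11
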