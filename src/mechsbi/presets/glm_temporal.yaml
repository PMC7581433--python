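# Temporal Bernoulli GLM: length-9 filter + bias, T=100 bins
model: glm_temporal
parameters: [bias, f1, f2, f3, f4, f5, f6, f7, f8, f9]
prior:
  kind: glm_smoothness
  filter_scale: 2.0
  bias_mean: 0.0
  bias_sd: 1.0
n_bins: 100
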