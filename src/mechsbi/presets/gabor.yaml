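# Gabor-parameterized Poisson GLM (V1 receptive field), transformed space
model: gabor
parameters: [log_gain, log_freq, log_aspect, log_width, logit_phase, logit_angle, logit_x, logit_y, bias]
prior:
  kind: gabor_transformed
  sd: [0.5, 0.5, 0.5, 0.5, 1.9, 1.78, 1.78, 1.78, 1.2767145334803704]
  mean: [0, 0, 0, 0, 0, 0, 0, 0, -0.57]
grid: 41
dt_s: 0.025
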