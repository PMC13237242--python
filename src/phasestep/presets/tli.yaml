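# Talbot-Lau interferometer preset: analyzer-period beat pattern,
# single harmonic stage, regularization-to-MSE ratio 100:1 (delta = 2).
scene: tli
period_W: 4.8          # µm
n_steps: 10
step_size: 0.5         # µm
visibility_floor: 1.0e-3
stages:
  - {n_harmonics: 1, half_range: 0.25, delta: 2}
optimizer:
  max_iterations: 100
  function_tolerance: 1.0e-9
  step_tolerance: 1.0e-6
simulate:
  shape: [128, 128]
  mean_counts: 10000.0
  step_error: 0.2      # µm, uniform half-width (motor accuracy scale)
  noise: poisson
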