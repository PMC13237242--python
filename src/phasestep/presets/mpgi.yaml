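# Modulated phase grating interferometer preset: directly resolvable
# fringes with envelope period W = 120 µm, three harmonic stages with
# narrowing search windows, regularization-to-MSE ratio 1:1 (delta = 0).
scene: mpgi
period_W: 120.0        # µm
n_steps: 10
step_size: 12.0        # µm
visibility_floor: 1.0e-3
stages:
  - {n_harmonics: 1, half_range: 12.0, delta: 0}
  - {n_harmonics: 2, half_range: 6.0, delta: 0}
  - {n_harmonics: 3, half_range: 3.0, delta: 0}
optimizer:
  max_iterations: 100
  function_tolerance: 1.0e-9
  step_tolerance: 1.0e-6
simulate:
  shape: [128, 128]
  mean_counts: 10000.0
  step_error: 4.0      # µm, uniform half-width
  noise: poisson
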