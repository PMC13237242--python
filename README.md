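# phasestep

Moiré-artifact reduction for phase-stepping grating interferometry.

X-ray grating interferometers (Talbot-Lau, modulated-phase-grating, and
related designs) retrieve three images per scan by comparing a sample and a
reference phase-stepping acquisition pixel by pixel: **attenuation**
`Γ = a0ˢ/a0ʳ`, **differential phase** `Δφ` (the fringe shift caused by
refraction), and **dark-field** `Σ = V₁ˢ/V₁ʳ` (the visibility loss caused
by small-angle scattering, with `V₁ = a₁/a₀`).  The standard retrieval
assumes the grating stops exactly at evenly spaced positions and that the
fringe is a pure sinusoid.  Real motors miss by fractions of a micron,
vibrations add more, and real fringes carry higher harmonics — the result
is a periodic residual (a Moiré artifact) superimposed on all three images.

`phasestep` removes the artifact by estimating the *true* step positions
from the data itself.  Each pixel's curve is fitted with a multi-harmonic
model

    I(x, y, x_g) = a₀ + Σₙ aₙ sin(2π n x_g / W + φₙ),      n = 1..n_H,

and the `n_xg` positions `x_g` are found by bounded minimization of the
mean-squared model error plus total-variation penalties on the refitted
maps — TV of every harmonic amplitude for the reference scan, TV of
`Γ`, `Δφ`, `Σ` themselves for the sample scan.  Penalty weights are
auto-calibrated so each term matches the MSE (times `10^δ`) at the start
of each stage.  The optimization runs in harmonic stages with narrowing
search windows; the sample fit anchors each pixel's basis on the reference
phases so `Δφ` is read off wrap-free.  A seeded synthetic fringe simulator
(step errors, sample contrast, Poisson noise) makes the whole pipeline
testable without beam time.

Intended users: people analysing phase-stepping interferometry data (or
developing retrieval methods) who need artifact-free `Γ`/`Δφ`/`Σ` images
and a controlled test bench.

## Worked example

Simulate a Talbot-Lau-like scan (64×64 pixels, 10 steps of 0.5 µm,
period W = 4.8 µm) with ±0.2 µm uniform step errors and Poisson noise,
analyse it naively, then correct the steps:

```python
import phasestep as ps

reference_truth, sample_truth, nominal = ps.make_tli_scene(shape=(64, 64))
true_ref = ps.perturb_steps(nominal, ps.StepErrorModel("uniform", 0.2, seed=0))
true_samp = ps.perturb_steps(nominal, ps.StepErrorModel("uniform", 0.2, seed=1))
ref_stack = ps.simulate_stack(reference_truth, true_ref, "poisson", seed=2)
samp_stack = ps.simulate_stack(sample_truth, true_samp, "poisson", seed=3)

# naive analysis at the nominal, evenly spaced positions
ref_fit = ps.fit_pixels(ref_stack, nominal, n_H=1)
samp_fit = ps.fit_pixels_anchored(samp_stack, nominal, 1, ref_fit)
naive = ps.compute_images(ref_fit, samp_fit)

# estimate the true positions, then re-form the images
stages = [ps.StageConfig(n_H=1, half_range=0.25, delta=2)]
ref_res, samp_res, images = ps.correct(ref_stack, samp_stack, nominal, stages)

print("sample steps: RMS error %.3f -> %.3f um" % (
    ps.step_recovery_error(nominal, true_samp),
    ps.step_recovery_error(samp_res.corrected_steps, true_samp)))
for name in ("attenuation", "dphase", "darkfield"):
    amp_n = ps.moire_amplitude(getattr(naive, name)[2:10].mean(axis=0)).amplitude
    amp_c = ps.moire_amplitude(getattr(images, name)[2:10].mean(axis=0)).amplitude
    print("%-12s Moire amplitude %.4f -> %.4f  (%.1fx smaller)"
          % (name, amp_n, amp_c, amp_n / amp_c))
```

Output:

```
sample steps: RMS error 0.121 -> 0.058 um
attenuation  Moire amplitude 0.0315 -> 0.0031  (10.1x smaller)
dphase       Moire amplitude 0.1079 -> 0.0134  (8.0x smaller)
darkfield    Moire amplitude 0.1095 -> 0.0056  (19.4x smaller)
```

The mean-aligned RMS step error halves (a uniform offset of all steps is
unobservable, so errors are compared after removing the mean), and the
amplitude of the residual ripple — measured by fitting a sinusoid to a
band-averaged line profile — drops by roughly an order of magnitude in all
three images.

## Command line

The same pipeline is available as a CLI:

```sh
phasestep simulate --config src/phasestep/presets/tli.yaml --out data/ --seed 5
phasestep correct  --reference data/reference_stack.tif \
                   --sample data/sample_stack.tif \
                   --config src/phasestep/presets/tli.yaml --out corrected/
phasestep evaluate --images corrected/ --line 0,8,127,8 --linewidth 9 \
                   --out report.tsv
```

`simulate` writes reference/sample TIFF stacks plus the ground-truth maps
and true step positions; `correct` writes corrected step files, parameter
maps, the three contrast images and their nominal-step counterparts;
`evaluate` writes a table of image variances (one-sided F-test) and
line-profile sinusoid amplitudes (one-sided Welch t-test), nominal vs
corrected.  Presets: `tli.yaml` (single stage, n_H = 1, ±0.25 µm, δ = 2),
`mpgi.yaml` (stages n_H = 1, 2, 3 at ±12/±6/±3 µm, δ = 0), and
`mpgi_synthetic.yaml` — see `docs/methods.md` for when to prefer harmonic
orders (1, 3, 3).

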