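# Methods

## The problem

A phase-stepping grating interferometer records, at each detector pixel, the
intensity of a periodic fringe pattern as a grating is translated laterally
through a series of positions `x_g`.  Fitting each pixel's phase-stepping
curve for a reference (empty-beam) and a sample acquisition yields three
images: attenuation `Γ = a0_s / a0_r`, differential phase `Δφ` (the
first-harmonic fringe shift), and dark-field `Σ = V1_s / V1_r` with
`V1 = a1 / a0` the fringe visibility.

The standard analysis assumes the steps are exactly at their commanded,
evenly spaced positions and that the fringe is a pure sinusoid.  Motor
inaccuracy and vibration violate the first assumption; diffraction physics
violates the second (the fringe carries higher harmonics).  Both leave
periodic residuals — Moiré artifacts — in all three images.  This package
removes them by treating the `n_xg` step positions as unknowns and
estimating them from the data.

## Model and estimator

Each pixel's curve is modelled as a truncated Fourier series with `n_H`
harmonics of the known period `W`:

    I(x, y, x_g) = a0(x, y) + Σ_n a_n(x, y) sin(2π n x_g / W + φ_n(x, y)),

linear in `A_n = a_n cos φ_n`, `B_n = a_n sin φ_n`, so one regression
operator `G = (BᵀB)⁻¹ Bᵀ` (built from the candidate step positions) fits
every pixel at once.  Amplitudes and phases are recovered with
`a_n = √(A_n² + B_n²)` and a two-argument arctangent, giving a unique
`φ_n ∈ (−π, π]`; when an amplitude is zero to round-off the phase is pinned
at 0 by convention.

For the sample acquisition the per-pixel reference phases are folded into
the basis arguments, so the fitted first-harmonic phase *is* the
differential phase directly — no subtraction of two independently wrapped
phases, hence no wraparound artifact near ±π.  The cost is a per-pixel
normal-equation solve (batched over pixels here, but mathematically
identical to independent per-pixel solves).

Step positions are estimated by bounded minimization of

    (1/N) Σ_{x,y,x_g} (I_m − Î)²  +  Σ_j λ_j R_j,        N = n_x n_y n_xg,

where the model `Î` is refitted from scratch at every candidate position
vector.  The penalties `R_j` are normalized anisotropic total variations
(TV) of the refitted maps:

* reference mode: `TV(a_n)` for every harmonic amplitude, the mean `a0`
  included — oscillations in any fitted amplitude map are penalized;
* sample mode: `TV(Γ) + TV(Δφ) + TV(Σ)` — the artifacts in the final
  images are penalized directly.

TV uses forward differences with open boundaries and the prefactor
`1/(n_x n_y)`; differences touching a pixel masked by the validity mask
(reference mean ≤ 0 or reference visibility below `visibility_floor`,
default 10⁻³) are skipped.

Each weight is calibrated at the stage's initial positions so that
`λ_j R_j = MSE · 10^δ` there, then frozen for the stage.  `δ` (an integer
order of magnitude) is the method's one free knob: it sets the
regularization-to-loss ratio.  A penalty that vanishes at the calibration
point gets weight 0 (it carries no signal there and the ratio would be
undefined).

### Harmonic stages

The minimization runs in stages of non-decreasing harmonic order and
non-increasing symmetric search window (a box of ± `half_range` around the
stage's initial positions).  Stage 1 starts from the nominal positions;
each later stage starts from the previous stage's result and recalibrates
its weights there.  A uniform translation of all positions is an exact flat
direction of the objective (the refit absorbs it into the phases), so
recovered positions are meaningful only up to a common offset; all
step-error metrics in `evaluate` therefore mean-align before comparing.

The optimizer is L-BFGS-B with a forward-difference gradient (increment
10⁻⁴ µm), relative function tolerance 10⁻⁹, a step tolerance of 10⁻⁶ µm
enforced through the iteration callback, and at most 100 iterations per
stage.  Objective values are non-increasing across accepted iterates and
the final positions never leave the stage's box.

### Choosing the stage schedule (and a caution)

Two shipped presets mirror the two laboratory instruments: `tli.yaml`
(W = 4.8 µm, 10 × 0.5 µm steps, one stage with n_H = 1, ±0.25 µm, δ = 2)
and `mpgi.yaml` (W = 120 µm, 10 × 12 µm steps, stages n_H = 1, 2, 3 with
windows ±12, ±6, ±3 µm, δ = 0).

The harmonic orders of the schedule should match the harmonic content of
the measured fringe (for directly resolved fringes, check the Fourier
spectrum).  Including a stage whose order covers a harmonic the fringe
does not contain invites a specific failure we characterised on synthetic
data: with 10 even steps spanning exactly one period, the harmonics are
mutually orthogonal at the *nominal* positions, so an under-parameterized
fit is aliasing-free there but aliased at the *true* (uneven) positions.
For a fringe with harmonics {1, 3}, an intermediate n_H = 2 stage then
prefers step configurations several µm from the truth where the images
merely *look* smooth: its sample-mode penalty involves only harmonics 0–1
and cannot see the second-harmonic coefficients absorbing third-harmonic
power.  (Reference mode is protected: `TV(a_2)` enters the penalty with a
large calibrated weight.)  The synthetic-MPGI preset
(`mpgi_synthetic.yaml`) therefore keeps the three narrowing windows but
uses harmonic orders (1, 3, 3).  With it, both acquisitions' positions are
recovered to ~1 % of the initial error and the Moiré amplitudes drop by
more than an order of magnitude; with an n_H = 2 stage inserted, the
sample correction can move *away* from the truth.  The general
recommendation stands: use the minimum set of harmonic orders the fringe
actually requires.

## Synthetic data

The simulator instantiates the harmonic model with spatially varying truth
maps:

    I = N₀ · T(x,y) · [1 + Σ_n v_n · s(x,y) · sin(2π n x_g / W + n·(ψ(x,y) + δφ(x,y)))]

with mean counts `N₀` (default 10⁴), transmission `T ∈ (0,1]`, visibility
scaling `s ∈ [0,1]`, harmonic fractions `v_n` (Σ v_n < 1), carrier phase
map `ψ` (a linear ramp: ~6 fringes across the field for the MPGI scene,
a slow 2-fringe beat for the TLI scene), and refraction shift `δφ`.
Harmonic `n` of a laterally shifted periodic pattern shifts by `n` times
the fundamental phase, hence the factor `n` on both `ψ` and `δφ` — a
thin-object modelling choice.  Step errors are i.i.d. uniform on
±`scale` (motor accuracy as a hard bound; a Gaussian option exists), and
counting noise is Poisson per frame.  All randomness is seeded.

Scene defaults: the MPGI-like fringe has `v = (0.40, 0.03, 0.12)` — a
third harmonic stronger than the second, as observed for
rectangular-envelope modulated phase gratings; the TLI-like fringe is a
single harmonic, `v = (0.35,)`.  The sample is a capsule phantom —
a scattering core (transmission 0.75, visibility scale 0.60), an absorbing
wall with little visibility loss (0.65 / 0.95), and a smooth 0.5 rad phase
bump — mimicking the signatures of a microsphere-filled capsule.

What the simulator does **not** model: wave-optics propagation and grating
diffraction (the harmonic fractions are inputs, not derived from a grating
design), source spectra, detector point-spread and gain nonuniformity,
dose fluctuations between frames, and scatter backgrounds.  Passing tests
on this bench therefore validate the estimator against its own forward
model with realistic noise and step errors — not against the full physics
of a beamline; on real data the fit residual contains model error, not
only noise, and `δ` may need adjustment (the shipped instrument presets
use the values that worked on the corresponding real systems).

## Evaluation metrics

* `image_variance`: unbiased variance over valid pixels; nominal vs
  corrected compared with a one-sided F-test ((n−1, n−1) degrees of
  freedom, upper tail).
* `moire_amplitude`: a line profile is fitted with offset + sine + cosine
  at the dominant discrete-Fourier frequency (zero bin excluded); the
  amplitude is the quadrature magnitude, its standard error propagated
  from the residual variance through the linear-fit covariance.  Profiles
  through the artifact are band-averaged over background rows to suppress
  counting noise.  Nominal vs corrected amplitudes are compared with a
  one-sided Welch t-test on the fit-derived standard errors (a reporting
  construction only; it never enters the correction loop).
* `step_recovery_error`: RMS of the mean-aligned difference between
  estimated and true positions (synthetic data only).

## Numerical choices and degenerate inputs

* All arithmetic in double precision; fits are exact reproductions of the
  generating parameters (≤ 10⁻⁸ relative) for noiseless in-class data.
* A design matrix with relative singular value below 10⁻¹⁰ (coincident
  steps, n_xg < 2 n_H + 1) raises `DegenerateDesignError`; nothing is
  silently pseudo-inverted.  The stage boxes keep candidates non-degenerate
  in practice.
* A non-finite objective value aborts the stage with the offending
  candidate positions in the message.
* Masked pixels are excluded from TV sums but the TV prefactor stays
  `1/(n_x n_y)`.
* The amplitude-zero phase convention uses a threshold of
  `eps^0.75 · max(|a0|, 1)` to absorb solver round-off.

## Problem sizes

The end-to-end synthetic runs (tests and the acceptance script) use
128 × 128-pixel frames with 10 phase steps — large enough that the TV
statistics are informative and the band-averaged line profiles resolve the
artifact, while a full three-stage reference + sample correction completes
in tens of seconds.

## Known limitations

* Local optimization only: with step errors approaching a half-period of
  the highest harmonic the true basin may not contain the nominal start.
* The sample-mode penalty cannot detect overfitting in harmonics ≥ 2 (see
  the stage-schedule caution above).
* No dose-fluctuation term: frame-to-frame flux variations masquerade as
  `a0` oscillations.
* `Δφ` is reported in (−π, π] with no spatial unwrapping.
* Weight calibration matches the *values* of the penalty terms to the MSE,
  not their gradients; `δ` absorbs the difference and is
  instrument-dependent.
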