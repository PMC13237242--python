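"""Synthetic phase-stepping data with controlled imperfections.

The forward model instantiates the multi-harmonic fringe model with
spatially varying parameters::

    I(x, y, x_g) = N0 * T(x,y) * [ 1 + sum_n v_n * s(x,y) *
                    sin(2 pi n x_g / W + n * (psi(x,y) + dphi(x,y))) ]

where ``N0`` is the mean count level, ``T`` the sample transmission,
``s`` the sample's visibility scaling (small-angle-scatter signature),
``v_n`` the harmonic amplitude fractions of the empty-beam fringe,
``psi`` the spatial carrier phase of the fringe pattern, and ``dphi`` the
refraction-induced fringe shift.  Harmonic ``n`` of a laterally shifted
periodic pattern is shifted by ``n`` times the fundamental phase, which is
why the carrier and sample phase both enter multiplied by ``n``.

Phase-step position errors (bounded random perturbations of the commanded
motor positions) plus multi-harmonic fringes are exactly the mechanism that
produces Moiré artifacts in the retrieved images, so a stack simulated with
``perturb_steps`` errors but *analysed at the nominal positions* exhibits
the artifact this package removes.

Two convenience scenes mirror the two laboratory instruments:

* Talbot-Lau-like (``make_tli_scene``): period 4.8 µm analysed as a beat
  pattern, 10 steps of 0.5 µm, single-harmonic-dominated fringe, slow
  carrier ramp.
* Modulated-phase-grating-like (``make_mpgi_scene``): envelope period
  120 µm, 10 steps of 12 µm, directly resolvable fringes with a third
  harmonic stronger than the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import FringeStack, StepVector

__all__ = [
    "PhantomTruth",
    "StepErrorModel",
    "perturb_steps",
    "simulate_stack",
    "make_tli_scene",
    "make_mpgi_scene",
]


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth maps from which a phase-stepping stack is generated."""

    transmission: np.ndarray  # (ny, nx), in (0, 1]
    phase_shift: np.ndarray  # (ny, nx), rad; harmonic n is shifted by n * phase_shift
    visibility_scale: np.ndarray  # (ny, nx), in [0, 1]
    v_n: np.ndarray  # (n_H,) harmonic amplitude fractions of the empty fringe
    carrier: np.ndarray  # (ny, nx) fundamental fringe phase map, rad
    mean_counts: float

    def __post_init__(self) -> None:
        t = np.asarray(self.transmission, float)
        p = np.asarray(self.phase_shift, float)
        s = np.asarray(self.visibility_scale, float)
        v = np.asarray(self.v_n, float)
        c = np.asarray(self.carrier, float)
        if not (t.shape == p.shape == s.shape == c.shape):
            raise ValueError("all truth maps must share one shape")
        for name, arr in (("transmission", t), ("phase_shift", p),
                          ("visibility_scale", s), ("carrier", c)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(t <= 0) or np.any(t > 1):
            raise ValueError("transmission must lie in (0, 1]")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("visibility_scale must lie in [0, 1]")
        if v.ndim != 1 or np.any(v < 0) or v.sum() >= 1:
            raise ValueError("v_n must be non-negative with sum < 1")
        if not (self.mean_counts > 0):
            raise ValueError("mean_counts must be positive")
        for attr, arr in (("transmission", t), ("phase_shift", p),
                          ("visibility_scale", s), ("v_n", v), ("carrier", c)):
            object.__setattr__(self, attr, arr)

    @property
    def n_H(self) -> int:
        return self.v_n.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmission.shape


@dataclass(frozen=True)
class StepErrorModel:
    """Random perturbation of the commanded grating positions.

    ``uniform`` draws i.i.d. errors on [-scale, +scale] (motor accuracy as a
    hard bound); ``gaussian`` draws N(0, scale^2).
    """

    distribution: str = "uniform"
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


def perturb_steps(nominal: StepVector, model: StepErrorModel) -> StepVector:
    """True grating positions: nominal plus i.i.d. errors, reproducible from seed."""
    rng = np.random.default_rng(model.seed)
    n = nominal.n_steps
    if model.distribution == "uniform":
        err = rng.uniform(-model.scale, model.scale, size=n)
    else:
        err = rng.normal(0.0, model.scale, size=n)
    return nominal.replace_positions(nominal.positions + err)


def expected_intensities(truth: PhantomTruth, true_steps: StepVector) -> np.ndarray:
    """Noise-free expected counts, shape (n_xg, ny, nx)."""
    n = np.arange(1, truth.n_H + 1)
    theta = 2.0 * np.pi * np.outer(true_steps.positions, n) / true_steps.period_W
    # fringe phase of harmonic n at each pixel: n * (carrier + phase_shift)
    pix_phase = truth.carrier + truth.phase_shift  # (ny, nx)
    arg = theta[:, :, None, None] + n[None, :, None, None] * pix_phase[None, None]
    modulation = np.einsum(
        "n,gnij->gij", truth.v_n, np.sin(arg), optimize=True
    ) * truth.visibility_scale[None]
    expected = truth.mean_counts * truth.transmission[None] * (1.0 + modulation)
    if expected.min() < 0:
        raise ValueError(
            "negative expected intensity: harmonic fractions v_n are too large "
            f"(min expectation {expected.min():.3g})"
        )
    return expected


def simulate_stack(
    truth: PhantomTruth,
    true_steps: StepVector,
    noise: str = "none",
    seed: int = 0,
) -> FringeStack:
    """Generate a measured stack at the (true) grating positions.

    ``noise='poisson'`` replaces each expected count with a Poisson draw;
    ``noise='none'`` returns the expectation itself.
    """
    expected = expected_intensities(truth, true_steps)
    if noise == "none":
        return FringeStack(expected)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        return FringeStack(rng.poisson(expected).astype(float))
    raise ValueError(f"unknown noise model {noise!r}")


def _capsule_maps(
    shape: tuple[int, int],
    transmission_core: float,
    transmission_wall: float,
    visibility_core: float,
    visibility_wall: float,
    phase_peak: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disk-in-annulus phantom: scattering core, absorbing wall, smooth phase.

    Mimics a capsule of sub-resolution microspheres: the core attenuates and
    strongly reduces visibility (dark-field), the wall attenuates with little
    visibility loss, and refraction produces a smooth fringe-shift profile.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_core = 0.22 * min(ny, nx)
    r_wall = 0.30 * min(ny, nx)

    transmission = np.ones(shape)
    transmission[r <= r_wall] = transmission_wall
    transmission[r <= r_core] = transmission_core
    visibility = np.ones(shape)
    visibility[r <= r_wall] = visibility_wall
    visibility[r <= r_core] = visibility_core
    # smooth both so edges span a few pixels (finite resolution)
    transmission = ndimage.gaussian_filter(transmission, 1.5)
    visibility = ndimage.gaussian_filter(visibility, 1.5)

    bump = np.where(r <= r_wall, 1.0, 0.0)
    phase = phase_peak * ndimage.gaussian_filter(bump, 4.0)
    return transmission, np.clip(visibility, 0.0, 1.0), phase


def _carrier_ramp(shape: tuple[int, int], cycles_x: float, cycles_y: float) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    return 2.0 * np.pi * (cycles_x * xx / nx + cycles_y * yy / ny)


def make_tli_scene(
    shape: tuple[int, int] = (128, 128),
    mean_counts: float = 1.0e4,
) -> tuple[PhantomTruth, PhantomTruth, StepVector]:
    """Talbot-Lau-like scene: W = 4.8 µm, 10 steps of 0.5 µm, one dominant harmonic.

    Returns (reference truth, sample truth, nominal steps).  The carrier is a
    slow ramp (about two beat fringes across the field), as the analyzer
    grating converts micron fringes into a slowly varying beat pattern.
    """
    carrier = _carrier_ramp(shape, cycles_x=2.0, cycles_y=0.3)
    v_n = np.array([0.35])
    ones = np.ones(shape)
    zeros = np.zeros(shape)
    reference = PhantomTruth(ones, zeros, ones, v_n, carrier, mean_counts)
    trans, vis, phase = _capsule_maps(shape, 0.75, 0.65, 0.60, 0.95, 0.5)
    sample = PhantomTruth(trans, phase, vis, v_n, carrier, mean_counts)
    nominal = StepVector(0.5 * np.arange(10), period_W=4.8, nominal_step=0.5)
    return reference, sample, nominal


def make_mpgi_scene(
    shape: tuple[int, int] = (128, 128),
    mean_counts: float = 1.0e4,
) -> tuple[PhantomTruth, PhantomTruth, StepVector]:
    """Modulated-phase-grating-like scene: W = 120 µm, 10 steps of 12 µm.

    The fringe carries harmonics 1-3 with the third stronger than the
    second, as observed for rectangular-envelope modulated phase gratings,
    and several directly resolvable fringes run across the field.
    """
    carrier = _carrier_ramp(shape, cycles_x=6.0, cycles_y=0.2)
    v_n = np.array([0.40, 0.03, 0.12])
    ones = np.ones(shape)
    zeros = np.zeros(shape)
    reference = PhantomTruth(ones, zeros, ones, v_n, carrier, mean_counts)
    trans, vis, phase = _capsule_maps(shape, 0.75, 0.65, 0.60, 0.95, 0.5)
    sample = PhantomTruth(trans, phase, vis, v_n, carrier, mean_counts)
    nominal = StepVector(12.0 * np.arange(10), period_W=120.0, nominal_step=12.0)
    return reference, sample, nominal
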