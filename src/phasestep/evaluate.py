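"""Quantification of Moiré artifacts and step-recovery accuracy.

The artifact manifests as a residual sinusoidal ripple in the retrieved
images.  Two complementary metrics are used: the variance across an image
(compared between nominal-step and corrected-step analyses with a one-sided
F-test) and the amplitude of a sinusoid fitted to a line profile crossing
the artifact (compared with a one-sided t-test on the fit-derived standard
errors).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

from .model import StepVector

__all__ = [
    "image_variance",
    "SinusoidFit",
    "moire_amplitude",
    "variance_f_test",
    "amplitude_t_test",
    "step_recovery_error",
    "line_profile",
]


def image_variance(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Unbiased sample variance over the valid pixels."""
    image = np.asarray(image, float)
    values = image.ravel() if mask is None else image[np.asarray(mask, bool)]
    if values.size < 2:
        raise ValueError(f"need at least 2 valid pixels, got {values.size}")
    return float(np.var(values, ddof=1))


class SinusoidFit(NamedTuple):
    amplitude: float
    period: float
    phase: float
    amplitude_se: float


def moire_amplitude(profile: np.ndarray) -> SinusoidFit:
    """Fit ``offset + A sin(2 pi t / period + phase)`` to a 1-D profile.

    The dominant period is located at the discrete-Fourier peak (zero bin
    excluded); amplitude and phase then come from a linear least-squares fit
    of offset + sine + cosine at that frequency.  The amplitude standard
    error is propagated from the residual variance through the linear-fit
    covariance (delta method on the quadrature sum).
    """
    profile = np.asarray(profile, float)
    if profile.ndim != 1 or profile.size < 8:
        raise ValueError("profile must be 1-D with at least 8 samples")
    n = profile.size
    if np.all(profile == 0):
        return SinusoidFit(0.0, float(n), 0.0, 0.0)

    spectrum = np.abs(np.fft.rfft(profile))
    k = int(np.argmax(spectrum[1:])) + 1  # exclude the zero-frequency bin
    t = np.arange(n)
    omega = 2.0 * np.pi * k / n
    design = np.column_stack([np.ones(n), np.sin(omega * t), np.cos(omega * t)])
    coef, *_ = np.linalg.lstsq(design, profile, rcond=None)
    _, alpha, beta = coef
    amplitude = float(np.hypot(alpha, beta))
    phase = float(np.arctan2(beta, alpha)) if amplitude > 0 else 0.0

    residual = profile - design @ coef
    dof = n - 3
    sigma2 = float(residual @ residual) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(design.T @ design)
    if amplitude > 0:
        grad = np.array([0.0, alpha, beta]) / amplitude
        amp_se = float(np.sqrt(grad @ cov @ grad))
    else:
        amp_se = float(np.sqrt(0.5 * (cov[1, 1] + cov[2, 2])))
    return SinusoidFit(amplitude, n / k, phase, amp_se)


def variance_f_test(
    var_nominal: float, var_corrected: float, n_pixels: int
) -> tuple[float, float]:
    """One-sided F-test of H_A: nominal variance > corrected variance.

    Returns (F, upper-tail p) with (n-1, n-1) degrees of freedom.
    """
    if var_nominal <= 0 or var_corrected <= 0:
        raise ValueError("variances must be positive")
    if n_pixels < 2:
        raise ValueError("need at least 2 pixels")
    f = var_nominal / var_corrected
    dof = n_pixels - 1
    return float(f), float(stats.f.sf(f, dof, dof))


def amplitude_t_test(
    amp_nominal: float,
    se_nominal: float,
    amp_corrected: float,
    se_corrected: float,
    dof_nominal: float | None = None,
    dof_corrected: float | None = None,
) -> tuple[float, float]:
    """One-sided Welch t-test of H_A: nominal amplitude > corrected amplitude.

    Uses the fit-derived standard errors of the two sinusoid amplitudes.
    With degrees of freedom supplied, the Welch-Satterthwaite approximation
    is used; otherwise the large-sample normal tail.
    """
    if se_nominal <= 0 or se_corrected <= 0:
        raise ValueError("standard errors must be positive")
    pooled = np.hypot(se_nominal, se_corrected)
    t = (amp_nominal - amp_corrected) / pooled
    if dof_nominal is not None and dof_corrected is not None:
        nu = pooled**4 / (
            se_nominal**4 / dof_nominal + se_corrected**4 / dof_corrected
        )
        p = stats.t.sf(t, nu)
    else:
        p = stats.norm.sf(t)
    return float(t), float(p)


def step_recovery_error(estimated: StepVector, truth: StepVector) -> float:
    """RMS position error after removing the mean offset (gauge alignment).

    A uniform translation of all steps is unobservable (the fit absorbs it
    into the phases), so only the mean-aligned residual is meaningful.
    """
    if estimated.n_steps != truth.n_steps:
        raise ValueError(
            f"length mismatch: {estimated.n_steps} vs {truth.n_steps}"
        )
    d = estimated.positions - truth.positions
    d = d - d.mean()
    return float(np.sqrt(np.mean(d**2)))


def line_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    linewidth: int = 1,
) -> np.ndarray:
    """Intensity profile along a line (row, col) -> (row, col), width-averaged."""
    from skimage.measure import profile_line

    return profile_line(
        np.asarray(image, float), start, end, linewidth=linewidth, mode="reflect"
    )
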