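"""Anisotropic total variation and the step-correction penalty terms.

The step-position objective is the mean-squared model error plus total
variation (TV) penalties that punish the oscillatory residuals a wrong set
of step positions imprints on the fitted maps:

* reference mode: the TV of each harmonic amplitude map ``a_n``, n = 0..n_H;
* sample mode:    the TV of the attenuation, differential-phase and
  dark-field images themselves.

Each penalty weight is calibrated once per harmonic stage so that, at the
stage's initial step positions, every weighted term matches the MSE scaled
by ``10**delta`` — the single free knob of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contrast import ContrastImages
from .model import HarmonicField

__all__ = [
    "PenaltyWeights",
    "total_variation",
    "reference_penalty",
    "sample_penalty",
    "calibrate_weights",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PenaltyWeights:
    """Calibrated weights for one harmonic stage.

    In reference mode ``weights`` has one entry per harmonic amplitude
    (n = 0 .. n_H); in sample mode it is ``(lambda_Gamma, lambda_dphi,
    lambda_Sigma)``.  ``delta`` is the order-of-magnitude scaling of the
    regularization relative to the MSE.
    """

    weights: np.ndarray
    delta: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and >= 0")
        object.__setattr__(self, "weights", w)


def total_variation(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized anisotropic total variation of a 2-D image.

    ``(1 / (n_x n_y)) * (sum |d_x f| + sum |d_y f|)`` with forward
    differences between adjacent pixels and open (non-periodic) boundaries.
    Differences that touch a masked-out pixel are skipped; the normalization
    stays ``1 / (n_x n_y)`` regardless of the mask.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("total_variation expects a 2-D image")
    if mask is None:
        if not np.all(np.isfinite(image)):
            raise ValueError("image contains non-finite values")
        dx = np.abs(np.diff(image, axis=1))
        dy = np.abs(np.diff(image, axis=0))
        return float((dx.sum() + dy.sum()) / image.size)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if not np.all(np.isfinite(image[mask])):
        raise ValueError("image contains non-finite values inside the mask")
    safe = np.where(mask, image, 0.0)
    dx = np.abs(np.diff(safe, axis=1)) * (mask[:, 1:] & mask[:, :-1])
    dy = np.abs(np.diff(safe, axis=0)) * (mask[1:, :] & mask[:-1, :])
    return float((dx.sum() + dy.sum()) / image.size)


def reference_amplitude_maps(fitted: HarmonicField) -> list[np.ndarray]:
    """The maps penalised in reference mode: a_0 and every a_n."""
    return [fitted.a0] + [fitted.amp[n] for n in range(fitted.n_H)]


def reference_penalty(fitted: HarmonicField, weights: PenaltyWeights) -> float:
    """Weighted TV of each harmonic amplitude map, the zeroth included."""
    maps = reference_amplitude_maps(fitted)
    if weights.weights.size != len(maps):
        raise ValueError(
            f"need {len(maps)} weights (harmonics 0..{fitted.n_H}), "
            f"got {weights.weights.size}"
        )
    return float(sum(w * total_variation(m) for w, m in zip(weights.weights, maps)))


def sample_penalty(images: ContrastImages, weights: PenaltyWeights) -> float:
    """Weighted TV of the attenuation, differential-phase and dark-field images."""
    if weights.weights.size != 3:
        raise ValueError(
            f"sample mode needs 3 weights (Gamma, dphi, Sigma), got {weights.weights.size}"
        )
    mask = images.validity_mask
    lam_g, lam_p, lam_s = weights.weights
    return float(
        lam_g * total_variation(images.attenuation, mask)
        + lam_p * total_variation(images.dphase, mask)
        + lam_s * total_variation(images.darkfield, mask)
    )


def calibrate_weights(
    mse_at_initial: float, penalties_at_initial: np.ndarray, delta: int
) -> PenaltyWeights:
    """Set each weight so that ``lambda_j * R_j = MSE * 10**delta`` at the anchor.

    ``penalties_at_initial`` are the raw (unit-weight) penalty terms R_j
    evaluated at the stage's initial step positions.  A term that vanishes
    there gets weight zero — it carries no signal at the anchor point and
    must not blow up the ratio.  The weights are then held fixed for every
    iteration of the stage.
    """
    if mse_at_initial < 0:
        raise ValueError("MSE must be >= 0")
    r = np.asarray(penalties_at_initial, dtype=float)
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("penalty terms must be finite and >= 0")
    lam = np.zeros_like(r)
    nonzero = r > 0
    lam[nonzero] = mse_at_initial / r[nonzero] * 10.0**delta
    for j in np.flatnonzero(~nonzero):
        logger.warning(
            "regularization term %d vanishes at the initial steps; its weight is set to 0",
            j,
        )
    return PenaltyWeights(weights=lam, delta=delta)
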