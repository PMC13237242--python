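"""Formation of the three interferometric contrast images.

Comparing a sample-scan harmonic fit against a reference (no-object) fit
yields, per pixel:

* attenuation  ``Gamma = a0_s / a0_r``      (transmission; conventional radiograph),
* differential phase ``dphi``               (lateral fringe shift from refraction),
* dark-field   ``Sigma = V1_s / V1_r``      (visibility loss from small-angle scatter),

with ``V1 = a1 / a0`` the first-harmonic visibility.  The differential phase
is taken directly from the anchored sample fit, where it is the fitted
first-harmonic phase offset and thus immune to the +/- pi wraparound of a
naive phase subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import HarmonicField

__all__ = ["ContrastImages", "compute_images", "DEFAULT_VISIBILITY_FLOOR"]

DEFAULT_VISIBILITY_FLOOR = 1e-3


@dataclass(frozen=True)
class ContrastImages:
    """The three contrast images and the mask of pixels where they are valid.

    Pixels where the reference fit carries no usable fringe signal
    (``a0_r <= 0`` or ``V1_r`` below the visibility floor) are flagged
    invalid; their values are set to the neutral background (1, 0, 1) so no
    non-finite numbers leak downstream, and total-variation sums skip them.
    """

    attenuation: np.ndarray
    dphase: np.ndarray
    darkfield: np.ndarray
    validity_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.attenuation.shape


def compute_images(
    reference: HarmonicField,
    sample_anchored: HarmonicField,
    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR,
) -> ContrastImages:
    """Form attenuation, differential-phase and dark-field images.

    Parameters
    ----------
    reference
        Plain (unanchored) fit of the reference scan.
    sample_anchored
        Fit of the sample scan anchored to ``reference``
        (:func:`phasestep.model.fit_pixels_anchored`); its first-harmonic
        phase is used directly as the differential phase.
    visibility_floor
        Reference pixels with ``V1_r`` below this are masked out: the
        dark-field ratio there is a division by (near) zero and carries no
        information.
    """
    if not sample_anchored.anchored:
        raise ValueError(
            "sample field is not anchored; fit it with fit_pixels_anchored "
            "against the reference so the differential phase is wrap-free"
        )
    if reference.shape != sample_anchored.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs sample {sample_anchored.shape}"
        )
    if reference.n_H < sample_anchored.n_H:
        raise ValueError(
            f"harmonic-order mismatch: reference n_H={reference.n_H} < "
            f"sample n_H={sample_anchored.n_H}"
        )

    a0_r, a0_s = reference.a0, sample_anchored.a0
    valid = a0_r > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        v1_r = np.where(valid, reference.amp[0] / np.where(valid, a0_r, 1.0), 0.0)
    valid &= v1_r >= visibility_floor
    valid &= a0_s > 0

    safe_a0r = np.where(valid, a0_r, 1.0)
    safe_v1r = np.where(valid, v1_r, 1.0)
    safe_a0s = np.where(valid, a0_s, 1.0)

    gamma = np.where(valid, a0_s / safe_a0r, 1.0)
    v1_s = sample_anchored.amp[0] / safe_a0s
    sigma = np.where(valid, v1_s / safe_v1r, 1.0)
    dphi = np.where(valid, sample_anchored.phase[0], 0.0)

    return ContrastImages(
        attenuation=gamma, dphase=dphi, darkfield=sigma, validity_mask=valid
    )
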