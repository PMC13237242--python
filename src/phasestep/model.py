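"""Multi-harmonic model of the phase-stepping curve and its per-pixel fit.

A phase-stepping acquisition records, at every detector pixel, the intensity
as a function of the lateral grating position ``x_g``.  The curve is modelled
as a truncated Fourier series in ``x_g`` with period ``W`` (the fringe /
envelope period of the interferometer)::

    I(x, y, x_g) = a_0(x, y) + sum_n a_n(x, y) * sin(2 pi n x_g / W + phi_n(x, y))

for harmonics ``n = 1 .. n_H``.  The model is linear in the coefficients
``A_n = a_n cos(phi_n)`` and ``B_n = a_n sin(phi_n)``, so the fit is a single
shared linear least-squares solve applied to every pixel's curve.

An *anchored* variant builds the sine/cosine basis with each pixel's
reference-scan phases folded into the argument; the fitted first-harmonic
phase is then directly the differential phase of the sample relative to the
reference, with no wrap-prone subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateDesignError",
    "StepVector",
    "FringeStack",
    "HarmonicField",
    "build_basis",
    "regression_operator",
    "fit_pixels",
    "fit_pixels_anchored",
    "evaluate_model",
]

# relative singular-value cutoff below which a design matrix is declared
# rank-deficient (coincident steps, too few steps, ...)
_RANK_RTOL = 1e-10


class DegenerateDesignError(np.linalg.LinAlgError):
    """The phase-step design matrix does not have full column rank."""


@dataclass(frozen=True)
class StepVector:
    """Grating positions of one phase-stepping scan.

    Parameters
    ----------
    positions : ndarray, shape (n_xg,)
        Grating positions in micrometres.  These are the optimisation
        variable of the step-correction algorithm.
    period_W : float
        Fringe (envelope / analyzer) period in micrometres.
    nominal_step : float
        The commanded step increment in micrometres (metadata; not used by
        the fit itself).
    """

    positions: np.ndarray
    period_W: float
    nominal_step: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or pos.size < 3:
            raise ValueError("need a 1-D vector of at least 3 step positions")
        if not np.all(np.isfinite(pos)):
            raise ValueError("step positions must be finite")
        if not (self.period_W > 0):
            raise ValueError(f"period_W must be positive, got {self.period_W}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_steps(self) -> int:
        return self.positions.size

    def shifted(self, delta: float) -> "StepVector":
        """Return a copy with every position translated by ``delta`` (µm)."""
        return StepVector(self.positions + delta, self.period_W, self.nominal_step)

    def replace_positions(self, positions: np.ndarray) -> "StepVector":
        return StepVector(np.asarray(positions, float), self.period_W, self.nominal_step)


@dataclass(frozen=True)
class FringeStack:
    """A stack of detector frames, one per phase step.

    ``intensities`` is indexed ``(step g, row y, column x)``; the fringe
    modulation runs along the column (x) axis.
    """

    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be a 3-D (n_xg, n_y, n_x) array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_xg(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_y(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_x(self) -> int:
        return self.intensities.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]


@dataclass(frozen=True)
class HarmonicField:
    """Per-pixel fitted harmonic parameters.

    Attributes
    ----------
    a0 : ndarray (n_y, n_x)
        Mean intensity (zeroth harmonic), counts.
    amp : ndarray (n_H, n_y, n_x)
        Harmonic amplitudes ``a_n >= 0``, counts.
    phase : ndarray (n_H, n_y, n_x)
        Harmonic phases ``phi_n`` in (-pi, pi].  For an anchored fit these
        are phase *offsets* from the reference scan; the first-harmonic
        offset is the differential-phase signal.
    linear : ndarray (n_y, n_x, 2 n_H + 1)
        Raw linear coefficients ``[a_0, A_1, B_1, ..., A_nH, B_nH]``.
    anchor_phase : ndarray (n_H, n_y, n_x) or None
        The per-pixel reference phases folded into the basis, when the fit
        was anchored; ``None`` for a plain fit.
    """

    a0: np.ndarray
    amp: np.ndarray
    phase: np.ndarray
    linear: np.ndarray
    n_H: int
    anchor_phase: np.ndarray | None = field(default=None)

    @property
    def anchored(self) -> bool:
        return self.anchor_phase is not None

    @property
    def shape(self) -> tuple[int, int]:
        return self.a0.shape

    @property
    def visibility(self) -> np.ndarray:
        """First-harmonic visibility ``V_1 = a_1 / a_0`` (invalid where a0 <= 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.a0 > 0, self.amp[0] / self.a0, np.nan)


def _check_fit_size(n_xg: int, n_H: int) -> None:
    if n_H < 1:
        raise ValueError("n_H must be >= 1")
    if n_xg < 2 * n_H + 1:
        raise DegenerateDesignError(
            f"{n_xg} phase steps cannot constrain {2 * n_H + 1} coefficients "
            f"(need n_xg >= 2 n_H + 1)"
        )


def _harmonic_args(steps: StepVector, n_H: int) -> np.ndarray:
    """theta[g, n-1] = 2 pi n x_g / W, shape (n_xg, n_H)."""
    n = np.arange(1, n_H + 1)
    return 2.0 * np.pi * np.outer(steps.positions, n) / steps.period_W


def build_basis(
    steps: StepVector, n_H: int, anchor_phases: np.ndarray | None = None
) -> np.ndarray:
    """Design matrix of the linearised harmonic model.

    Column 0 is all ones; columns (2n-1, 2n) hold ``sin`` and ``cos`` of
    ``2 pi n x_g / W`` for harmonic n, with ``anchor_phases[n-1]`` added to
    the argument when anchoring.

    Returns
    -------
    ndarray, shape (n_xg, 2 n_H + 1)
    """
    _check_fit_size(steps.n_steps, n_H)
    theta = _harmonic_args(steps, n_H)
    if anchor_phases is not None:
        anchor = np.asarray(anchor_phases, dtype=float)
        if anchor.shape != (n_H,):
            raise ValueError(f"anchor_phases must have shape ({n_H},), got {anchor.shape}")
        theta = theta + anchor[None, :]
    basis = np.empty((steps.n_steps, 2 * n_H + 1), dtype=float)
    basis[:, 0] = 1.0
    basis[:, 1::2] = np.sin(theta)
    basis[:, 2::2] = np.cos(theta)
    return basis


def regression_operator(basis: np.ndarray) -> np.ndarray:
    """Least-squares operator ``G = (B^T B)^-1 B^T``.

    Raises
    ------
    DegenerateDesignError
        If the basis is column-rank deficient (e.g. coincident steps); no
        silent pseudo-inversion is performed.
    """
    basis = np.asarray(basis, dtype=float)
    sv = np.linalg.svd(basis, compute_uv=False)
    if sv[-1] <= _RANK_RTOL * sv[0]:
        raise DegenerateDesignError(
            f"design matrix of shape {basis.shape} is rank deficient "
            f"(singular values {sv}); check for coincident or too few steps"
        )
    bt_b = basis.T @ basis
    return np.linalg.solve(bt_b, basis.T)


def _coeffs_to_field(
    coeffs: np.ndarray, n_H: int, anchor_phase: np.ndarray | None = None
) -> HarmonicField:
    """Transform linear coefficients (n_y, n_x, 2 n_H + 1) to amplitude/phase."""
    a0 = coeffs[..., 0]
    a_cos = np.moveaxis(coeffs[..., 1::2], -1, 0)  # A_n, (n_H, ny, nx)
    a_sin = np.moveaxis(coeffs[..., 2::2], -1, 0)  # B_n
    amp = np.hypot(a_cos, a_sin)
    # two-argument arctangent: unique phase in (-pi, pi].  An amplitude that
    # is zero up to round-off of the solve leaves the phase undefined; the
    # convention pins it at 0 there (threshold well below any real signal,
    # relative to the curve's mean level).
    phase = np.arctan2(a_sin, a_cos)
    phase = np.where(phase <= -np.pi, np.pi, phase)
    tiny = np.finfo(float).eps ** 0.75 * np.maximum(np.abs(a0), 1.0)
    phase = np.where(amp <= tiny, 0.0, phase)
    return HarmonicField(
        a0=a0, amp=amp, phase=phase, linear=coeffs, n_H=n_H, anchor_phase=anchor_phase
    )


def fit_pixels(stack: FringeStack, steps: StepVector, n_H: int) -> HarmonicField:
    """Fit every pixel's phase-stepping curve with one shared operator."""
    if stack.n_xg != steps.n_steps:
        raise ValueError(
            f"stack has {stack.n_xg} frames but step vector has {steps.n_steps} positions"
        )
    op = regression_operator(build_basis(steps, n_H))
    # (p, g) @ (g, ny*nx) -> (p, ny, nx) -> (ny, nx, p)
    flat = stack.intensities.reshape(stack.n_xg, -1)
    coeffs = np.moveaxis((op @ flat).reshape(-1, stack.n_y, stack.n_x), 0, -1)
    return _coeffs_to_field(coeffs, n_H)


def fit_pixels_anchored(
    stack: FringeStack, steps: StepVector, n_H: int, reference: HarmonicField
) -> HarmonicField:
    """Per-pixel fit with the reference phases folded into the basis.

    The basis (and hence the normal-equation inverse) becomes pixel-specific,
    so each pixel carries its own small solve; they are batched here but the
    result is identical to naive per-pixel least squares.  The fitted
    ``phase`` arrays are offsets from ``reference`` — ``phase[0]`` is the
    differential-phase image, free of the +/- pi wraparound a subtraction of
    independently fitted phases would suffer.
    """
    if stack.n_xg != steps.n_steps:
        raise ValueError(
            f"stack has {stack.n_xg} frames but step vector has {steps.n_steps} positions"
        )
    if reference.n_H < n_H:
        raise ValueError(
            f"reference fitted with n_H={reference.n_H} cannot anchor a fit "
            f"with n_H={n_H}"
        )
    if reference.shape != stack.frame_shape:
        raise ValueError(
            f"reference shape {reference.shape} != stack frame shape {stack.frame_shape}"
        )
    _check_fit_size(stack.n_xg, n_H)

    theta = _harmonic_args(steps, n_H)  # (g, n)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    npix = stack.n_y * stack.n_x
    ref_phase = reference.phase[:n_H].reshape(n_H, npix).T  # (pix, n)
    cos_r, sin_r = np.cos(ref_phase), np.sin(ref_phase)

    p = 2 * n_H + 1
    basis = np.empty((npix, stack.n_xg, p), dtype=float)
    basis[:, :, 0] = 1.0
    # sin(theta + phi_r), cos(theta + phi_r) via angle addition: no per-pixel
    # transcendentals, only broadcasted multiply-adds
    basis[:, :, 1::2] = sin_t[None] * cos_r[:, None, :] + cos_t[None] * sin_r[:, None, :]
    basis[:, :, 2::2] = cos_t[None] * cos_r[:, None, :] - sin_t[None] * sin_r[:, None, :]

    intens = stack.intensities.reshape(stack.n_xg, npix).T  # (pix, g)
    bt_b = np.einsum("pgi,pgj->pij", basis, basis, optimize=True)
    bt_y = np.einsum("pgi,pg->pi", basis, intens, optimize=True)
    try:
        coeffs = np.linalg.solve(bt_b, bt_y[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise DegenerateDesignError(f"anchored per-pixel design is singular: {exc}") from exc
    coeffs = coeffs.reshape(stack.n_y, stack.n_x, p)
    anchor = reference.phase[:n_H].copy()
    return _coeffs_to_field(coeffs, n_H, anchor_phase=anchor)


def evaluate_model(fitted: HarmonicField, steps: StepVector) -> FringeStack:
    """Predicted intensity stack from a fitted harmonic field."""
    _check_fit_size(steps.n_steps, fitted.n_H)
    theta = _harmonic_args(steps, fitted.n_H)  # (g, n)
    total_phase = fitted.phase
    if fitted.anchor_phase is not None:
        total_phase = total_phase + fitted.anchor_phase
    # (g, n, 1, 1) + (n, ny, nx) -> sum over n
    arg = theta[:, :, None, None] + total_phase[None, :, :, :]
    pred = fitted.a0[None, :, :] + np.einsum(
        "nij,gnij->gij", fitted.amp, np.sin(arg), optimize=True
    )
    return FringeStack(np.maximum(pred, 0.0))


def predicted_intensities(fitted: HarmonicField, steps: StepVector) -> np.ndarray:
    """Raw model prediction (may be slightly negative for pathological fits).

    ``evaluate_model`` clips at zero to honour the stack invariant; the
    objective function needs the unclipped prediction for residuals.
    """
    _check_fit_size(steps.n_steps, fitted.n_H)
    theta = _harmonic_args(steps, fitted.n_H)
    total_phase = fitted.phase
    if fitted.anchor_phase is not None:
        total_phase = total_phase + fitted.anchor_phase
    arg = theta[:, :, None, None] + total_phase[None, :, :, :]
    return fitted.a0[None, :, :] + np.einsum(
        "nij,gnij->gij", fitted.amp, np.sin(arg), optimize=True
    )
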