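"""Iterative estimation of the true phase-step positions.

A wrong assumption of evenly spaced grating positions leaves periodic
residuals (Moiré artifacts) in every fitted map.  The estimator treats the
``n_xg`` grating positions as unknowns and minimizes

    (1/N) * sum_{x, y, x_g} (I_m - I_model)^2  +  sum_j lambda_j R_j

over the positions, where ``N = n_x * n_y * n_xg``, the model is refitted
from scratch at every candidate position vector, and the penalties R_j are
total variations of the refitted maps (harmonic amplitudes in reference
mode; the three contrast images in sample mode).

The minimization runs in *harmonic stages*: first with a single harmonic
over a wide symmetric search window, then with more harmonics over
progressively narrower windows — the window narrowing regularizes what
would otherwise be an ill-posed multi-harmonic fit.  Each stage seeds the
next with its corrected positions, and the penalty weights are recalibrated
at each stage's initial positions and then frozen for the stage.

A uniform translation of all positions is a flat (gauge) direction of the
objective — the refit absorbs it into the fitted phases — so corrected
positions are only meaningful up to a common offset; comparisons against
ground truth must be made after mean-alignment.  No gauge constraint is
imposed; the box bounds limit the drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .contrast import DEFAULT_VISIBILITY_FLOOR, ContrastImages, compute_images
from .model import (
    FringeStack,
    HarmonicField,
    StepVector,
    fit_pixels,
    fit_pixels_anchored,
    predicted_intensities,
)
from .regularization import (
    PenaltyWeights,
    calibrate_weights,
    reference_amplitude_maps,
    total_variation,
)

__all__ = [
    "StageConfig",
    "StageTrace",
    "CorrectionResult",
    "objective",
    "objective_terms",
    "run_stage",
    "correct",
]

logger = logging.getLogger(__name__)

# forward-difference increment for the numerical gradient, in micrometres
FD_STEP_UM = 1e-4


@dataclass(frozen=True)
class StageConfig:
    """Settings of one harmonic stage.

    half_range is the symmetric search window (µm) about the stage's initial
    positions; delta sets the regularization-to-MSE ratio to ``10**delta``.
    """

    n_H: int
    half_range: float
    delta: int = 0
    max_iterations: int = 100
    function_tolerance: float = 1e-9
    step_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_H < 1:
            raise ValueError("n_H must be >= 1")
        if not (self.half_range > 0):
            raise ValueError("half_range must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (self.function_tolerance > 0 and self.step_tolerance > 0):
            raise ValueError("tolerances must be positive")


@dataclass
class StageTrace:
    """Per-stage optimization record."""

    n_H: int
    iterations: int
    objective_values: list[float]
    weights: PenaltyWeights
    initial_objective: float
    final_objective: float


@dataclass
class CorrectionResult:
    """Output of the multi-stage correction of one acquisition."""

    corrected_steps: StepVector
    per_stage_trace: list[StageTrace]
    per_stage_steps: list[StepVector]
    final_field: HarmonicField
    final_images: ContrastImages | None = None


def _validate_stages(stages: list[StageConfig]) -> None:
    if not stages:
        raise ValueError("stage list must be non-empty")
    for prev, nxt in zip(stages, stages[1:]):
        if nxt.n_H < prev.n_H:
            raise ValueError("stages must have non-decreasing n_H")
        if nxt.half_range > prev.half_range:
            raise ValueError("stages must have non-increasing half_range")


def objective_terms(
    candidate_steps: StepVector,
    stack: FringeStack,
    mode: str,
    n_H: int,
    reference_field: HarmonicField | None = None,
    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR,
) -> tuple[float, np.ndarray, HarmonicField, ContrastImages | None]:
    """Refit at the candidate positions and return (MSE, raw penalties, field, images).

    The raw penalties are the unit-weight regularization terms R_j: TVs of
    a_0..a_nH in reference mode, TVs of (Gamma, dphi, Sigma) in sample mode.
    """
    if mode not in ("reference", "sample"):
        raise ValueError(f"mode must be 'reference' or 'sample', got {mode!r}")
    if mode == "sample":
        if reference_field is None:
            raise ValueError("sample mode requires a reference_field")
        fitted = fit_pixels_anchored(stack, candidate_steps, n_H, reference_field)
    else:
        fitted = fit_pixels(stack, candidate_steps, n_H)
    residual = stack.intensities - predicted_intensities(fitted, candidate_steps)
    mse = float(np.mean(residual**2))
    if mode == "reference":
        raw = np.array([total_variation(m) for m in reference_amplitude_maps(fitted)])
        return mse, raw, fitted, None
    images = compute_images(reference_field, fitted, visibility_floor)
    mask = images.validity_mask
    raw = np.array(
        [
            total_variation(images.attenuation, mask),
            total_variation(images.dphase, mask),
            total_variation(images.darkfield, mask),
        ]
    )
    return mse, raw, fitted, images


def objective(
    candidate_steps: StepVector,
    stack: FringeStack,
    mode: str,
    n_H: int,
    weights: PenaltyWeights,
    reference_field: HarmonicField | None = None,
    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR,
) -> float:
    """MSE plus weighted penalties at the candidate step positions."""
    mse, raw, _, _ = objective_terms(
        candidate_steps, stack, mode, n_H, reference_field, visibility_floor
    )
    if weights.weights.size != raw.size:
        raise ValueError(
            f"{raw.size} penalty terms but {weights.weights.size} weights"
        )
    return mse + float(weights.weights @ raw)


def run_stage(
    stack: FringeStack,
    initial_steps: StepVector,
    stage: StageConfig,
    mode: str,
    reference_field: HarmonicField | None = None,
    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR,
    stage_index: int = 0,
) -> CorrectionResult:
    """One harmonic stage: calibrate weights, then bounded local descent.

    The penalty weights are calibrated at ``initial_steps`` (so that each
    weighted term equals MSE * 10**delta there) and held fixed.  The
    positions are then optimized within ``initial +/- half_range`` by L-BFGS-B
    with a forward-difference gradient, stopping on the relative function
    tolerance, on a maximum position update below ``step_tolerance``, or at
    ``max_iterations``.
    """
    mse0, raw0, _, _ = objective_terms(
        initial_steps, stack, mode, stage.n_H, reference_field, visibility_floor
    )
    weights = calibrate_weights(mse0, raw0, stage.delta)

    x0 = initial_steps.positions.copy()
    bounds = [(x - stage.half_range, x + stage.half_range) for x in x0]

    def fun(x: np.ndarray) -> float:
        steps = initial_steps.replace_positions(x)
        value = objective(
            steps, stack, mode, stage.n_H, weights, reference_field, visibility_floor
        )
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite objective {value} at candidate steps {x.tolist()}"
            )
        return value

    trace_values: list[float] = [fun(x0)]
    state = {"prev_x": x0.copy(), "iters": 0}

    def callback(intermediate_result) -> None:
        x = np.asarray(intermediate_result.x, float)
        f = float(intermediate_result.fun)
        state["iters"] += 1
        trace_values.append(f)
        mse, raw, _, _ = objective_terms(
            initial_steps.replace_positions(x), stack, mode, stage.n_H,
            reference_field, visibility_floor,
        )
        lam_r = weights.weights * raw
        logger.info(
            "stage=%d mode=%s n_H=%d iter=%d mse=%.8e penalties=%s objective=%.8e",
            stage_index, mode, stage.n_H, state["iters"], mse,
            np.array2string(lam_r, precision=6), f,
        )
        dx = np.max(np.abs(x - state["prev_x"]))
        state["prev_x"] = x.copy()
        if dx < stage.step_tolerance:
            raise StopIteration

    result = minimize(
        fun,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        callback=callback,
        options={
            "maxiter": stage.max_iterations,
            "ftol": stage.function_tolerance,
            "eps": FD_STEP_UM,
        },
    )
    x_final = np.clip(result.x, [b[0] for b in bounds], [b[1] for b in bounds])
    final_value = fun(x_final)
    # L-BFGS-B only accepts descent steps, but guard the contract explicitly
    if final_value > trace_values[0]:
        x_final = x0
        final_value = trace_values[0]
    corrected = initial_steps.replace_positions(x_final)

    mse_f, raw_f, fitted, images = objective_terms(
        corrected, stack, mode, stage.n_H, reference_field, visibility_floor
    )
    trace = StageTrace(
        n_H=stage.n_H,
        iterations=state["iters"],
        objective_values=trace_values,
        weights=weights,
        initial_objective=trace_values[0],
        final_objective=final_value,
    )
    return CorrectionResult(
        corrected_steps=corrected,
        per_stage_trace=[trace],
        per_stage_steps=[corrected],
        final_field=fitted,
        final_images=images,
    )


def _run_stages(
    stack: FringeStack,
    nominal_steps: StepVector,
    stages: list[StageConfig],
    mode: str,
    reference_field: HarmonicField | None,
    visibility_floor: float,
) -> CorrectionResult:
    steps = nominal_steps
    traces: list[StageTrace] = []
    per_stage_steps: list[StepVector] = []
    last: CorrectionResult | None = None
    for k, stage in enumerate(stages, start=1):
        last = run_stage(
            stack, steps, stage, mode, reference_field, visibility_floor, stage_index=k
        )
        steps = last.corrected_steps
        traces.extend(last.per_stage_trace)
        per_stage_steps.append(steps)
    assert last is not None
    return CorrectionResult(
        corrected_steps=steps,
        per_stage_trace=traces,
        per_stage_steps=per_stage_steps,
        final_field=last.final_field,
        final_images=last.final_images,
    )


def correct(
    reference_stack: FringeStack,
    sample_stack: FringeStack,
    nominal_steps: StepVector,
    stages: list[StageConfig],
    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR,
) -> tuple[CorrectionResult, CorrectionResult, ContrastImages]:
    """Full pipeline: correct reference steps, then sample steps, then images.

    1. The reference acquisition's positions are corrected stage by stage
       (each stage seeded by the previous stage's result).
    2. The reference field is refitted at the corrected positions with the
       final stage's harmonic order.
    3. The sample acquisition's positions are corrected likewise, starting
       again from the nominal positions (its motor errors are independent),
       with per-pixel fits anchored to the final reference field and the
       contrast-image TV penalty.
    4. The three contrast images are formed from the corrected fits.
    """
    _validate_stages(stages)
    if reference_stack.intensities.shape != sample_stack.intensities.shape:
        raise ValueError("reference and sample stacks must share geometry")

    ref_result = _run_stages(
        reference_stack, nominal_steps, stages, "reference", None, visibility_floor
    )
    n_H_final = stages[-1].n_H
    reference_field = fit_pixels(reference_stack, ref_result.corrected_steps, n_H_final)
    ref_result.final_field = reference_field

    samp_result = _run_stages(
        sample_stack, nominal_steps, stages, "sample", reference_field, visibility_floor
    )
    sample_field = fit_pixels_anchored(
        sample_stack, samp_result.corrected_steps, n_H_final, reference_field
    )
    images = compute_images(reference_field, sample_field, visibility_floor)
    samp_result.final_field = sample_field
    samp_result.final_images = images
    return ref_result, samp_result, images
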