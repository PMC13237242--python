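"""Shared fixtures.

The heavyweight end-to-end correction runs are session-scoped so the
artifact-reduction and stage-monotonicity checks share one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import phasestep as ps
from phasestep.contrast import compute_images
from phasestep.correction import StageConfig, correct
from phasestep.model import fit_pixels, fit_pixels_anchored


def band_profile(image: np.ndarray, rows: slice = slice(4, 20)) -> np.ndarray:
    """Row-band-averaged horizontal profile through the artifact region.

    The synthetic carrier runs along x, so averaging a band of background
    rows suppresses counting noise while keeping the Moiré ripple coherent.
    """
    return np.asarray(image, float)[rows].mean(axis=0)


@dataclass
class PipelineRun:
    nominal: ps.StepVector
    true_ref: ps.StepVector
    true_samp: ps.StepVector
    ref_stack: ps.FringeStack
    samp_stack: ps.FringeStack
    images_nominal: ps.ContrastImages
    ref_result: ps.CorrectionResult
    samp_result: ps.CorrectionResult
    images_corrected: ps.ContrastImages
    n_H: int


def _run_pipeline(scene, shape, step_error, seeds, stages, n_H) -> PipelineRun:
    ref_truth, samp_truth, nominal = scene(shape=shape)
    true_ref = ps.perturb_steps(nominal, ps.StepErrorModel("uniform", step_error, seed=seeds[0]))
    true_samp = ps.perturb_steps(nominal, ps.StepErrorModel("uniform", step_error, seed=seeds[1]))
    ref_stack = ps.simulate_stack(ref_truth, true_ref, "poisson", seed=seeds[2])
    samp_stack = ps.simulate_stack(samp_truth, true_samp, "poisson", seed=seeds[3])

    ref_nom = fit_pixels(ref_stack, nominal, n_H)
    samp_nom = fit_pixels_anchored(samp_stack, nominal, n_H, ref_nom)
    images_nominal = compute_images(ref_nom, samp_nom)

    ref_res, samp_res, images_corrected = correct(ref_stack, samp_stack, nominal, stages)
    return PipelineRun(
        nominal, true_ref, true_samp, ref_stack, samp_stack,
        images_nominal, ref_res, samp_res, images_corrected, n_H,
    )


@pytest.fixture(scope="session")
def mpgi_run() -> PipelineRun:
    """Modulated-phase-grating scene, 128x128, uniform +/-4 µm step errors,
    Poisson noise at 1e4 counts, three narrowing stages with harmonic orders
    matched to the scene's harmonic content {1, 3}."""
    stages = [
        StageConfig(n_H=1, half_range=12.0, delta=0),
        StageConfig(n_H=3, half_range=6.0, delta=0),
        StageConfig(n_H=3, half_range=3.0, delta=0),
    ]
    return _run_pipeline(
        ps.make_mpgi_scene, (128, 128), 4.0, (11, 12, 13, 14), stages, n_H=3
    )


@pytest.fixture(scope="session")
def tli_run() -> PipelineRun:
    """Talbot-Lau scene, single-harmonic fringe, uniform +/-0.2 µm step
    errors, Poisson noise at 1e4 counts, one stage (n_H=1, +/-0.25 µm, delta=2)."""
    stages = [StageConfig(n_H=1, half_range=0.25, delta=2)]
    return _run_pipeline(
        ps.make_tli_scene, (128, 128), 0.2, (21, 22, 23, 24), stages, n_H=1
    )
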