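"""Multi-harmonic fringe model: basis, regression, per-pixel fits."""

import numpy as np
import pytest

import phasestep as ps
from phasestep.model import predicted_intensities


def wrap(angle):
    """Principal value in (-pi, pi]."""
    a = np.mod(np.asarray(angle) + np.pi, 2 * np.pi) - np.pi
    return np.where(a <= -np.pi, np.pi, a)


def random_field(shape, n_H, rng, a0_level=100.0):
    a0 = a0_level * (1 + 0.1 * rng.uniform(-1, 1, shape))
    amp = 0.2 * a0_level * rng.uniform(0.2, 1.0, (n_H, *shape)) / n_H
    phase = wrap(rng.uniform(-np.pi, np.pi, (n_H, *shape)))
    return ps.HarmonicField(a0=a0, amp=amp, phase=phase, linear=None, n_H=n_H)


class TestBasis:
    def test_quarter_period_rows(self):
        steps = ps.StepVector(np.array([0.0, 30.0, 60.0, 90.0]), period_W=120.0)
        basis = ps.build_basis(steps, 1)
        np.testing.assert_allclose(basis[1], [1.0, 1.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(basis[0], [1.0, 0.0, 1.0], atol=1e-15)

    def test_anchor_phase_moves_into_argument(self):
        steps = ps.StepVector(np.array([0.0, 30.0, 60.0, 90.0]), period_W=120.0)
        basis = ps.build_basis(steps, 1, anchor_phases=np.array([np.pi / 2]))
        np.testing.assert_allclose(basis[0], [1.0, 1.0, 0.0], atol=1e-15)

    def test_column_layout_two_harmonics(self):
        steps = ps.StepVector(np.array([5.0, 17.0, 31.0, 55.0, 78.0]), period_W=120.0)
        basis = ps.build_basis(steps, 2)
        theta = 2 * np.pi * steps.positions / 120.0
        np.testing.assert_allclose(basis[:, 1], np.sin(theta))
        np.testing.assert_allclose(basis[:, 4], np.cos(2 * theta))

    def test_too_few_steps_rejected(self):
        steps = ps.StepVector(np.array([0.0, 30.0, 60.0, 90.0]), period_W=120.0)
        with pytest.raises(ps.DegenerateDesignError):
            ps.build_basis(steps, 2)


class TestRegressionOperator:
    def test_orthogonal_design_gives_identity(self):
        steps = ps.StepVector(np.arange(4) * 30.0, period_W=120.0)
        basis = ps.build_basis(steps, 1)
        op = ps.regression_operator(basis)
        np.testing.assert_allclose(op @ basis, np.eye(3), atol=1e-12)

    def test_constant_vector_maps_to_offset_coefficient(self):
        steps = ps.StepVector(np.arange(4) * 30.0, period_W=120.0)
        op = ps.regression_operator(ps.build_basis(steps, 1))
        np.testing.assert_allclose(op @ np.full(4, 7.5), [7.5, 0.0, 0.0], atol=1e-12)

    def test_coincident_steps_rejected(self):
        steps = ps.StepVector(np.zeros(4) + 3.0, period_W=120.0)
        with pytest.raises(ps.DegenerateDesignError):
            ps.regression_operator(ps.build_basis(steps, 1))


class TestFitPixels:
    @pytest.mark.parametrize("n_H", [1, 2, 3])
    def test_exact_recovery_in_model_class(self, n_H):
        """Noiseless data generated by the model is refit exactly."""
        rng = np.random.default_rng(42 + n_H)
        positions = np.sort(rng.uniform(0, 110, 10))
        steps = ps.StepVector(positions, period_W=120.0)
        truth = random_field((5, 6), n_H, rng)
        stack = ps.evaluate_model(truth, steps)
        fitted = ps.fit_pixels(stack, steps, n_H)
        np.testing.assert_allclose(fitted.a0, truth.a0, rtol=1e-8)
        np.testing.assert_allclose(fitted.amp, truth.amp, rtol=1e-8)
        np.testing.assert_allclose(
            wrap(fitted.phase - truth.phase), 0.0, atol=1e-8
        )

    def test_constant_stack(self):
        steps = ps.StepVector(np.arange(10) * 12.0, period_W=120.0)
        stack = ps.FringeStack(np.full((10, 3, 3), 50.0))
        fitted = ps.fit_pixels(stack, steps, 2)
        np.testing.assert_allclose(fitted.a0, 50.0, atol=1e-10)
        np.testing.assert_allclose(fitted.amp, 0.0, atol=1e-10)
        np.testing.assert_allclose(fitted.phase, 0.0)  # convention at zero amplitude

    def test_underfit_harmonic_matches_dft_bin(self):
        """With evenly spaced steps over one period, the fitted first-harmonic
        amplitude equals the first DFT bin magnitude of the 10-sample curve."""
        steps = ps.StepVector(np.arange(10) * 12.0, period_W=120.0)
        field = ps.HarmonicField(
            a0=np.full((1, 1), 100.0),
            amp=np.array([[[20.0]], [[0.0]], [[7.0]]]),
            phase=np.array([[[0.4]], [[0.0]], [[-1.1]]]),
            linear=None,
            n_H=3,
        )
        stack = ps.evaluate_model(field, steps)
        fitted = ps.fit_pixels(stack, steps, 1)
        curve = stack.intensities[:, 0, 0]
        dft_amp = 2.0 * np.abs(np.fft.rfft(curve)[1]) / curve.size
        np.testing.assert_allclose(fitted.amp[0, 0, 0], dft_amp, rtol=1e-10)

    def test_residual_monotone_in_harmonic_order(self):
        """Adding harmonics to the fit never increases the residual."""
        rng = np.random.default_rng(7)
        steps = ps.StepVector(np.sort(rng.uniform(0, 115, 10)), period_W=120.0)
        stack = ps.FringeStack(rng.uniform(50, 150, (10, 4, 4)))
        prev = np.inf
        for n_H in (1, 2, 3, 4):
            fitted = ps.fit_pixels(stack, steps, n_H)
            resid = np.sum((stack.intensities - predicted_intensities(fitted, steps)) ** 2)
            assert resid <= prev + 1e-9
            prev = resid


class TestAnchoredFit:
    @pytest.fixture
    def reference(self):
        rng = np.random.default_rng(3)
        steps = ps.StepVector(np.sort(rng.uniform(0, 110, 10)), period_W=120.0)
        truth = random_field((4, 5), 2, rng)
        stack = ps.evaluate_model(truth, steps)
        return steps, ps.fit_pixels(stack, steps, 2), stack

    def test_identical_stack_gives_zero_offsets(self, reference):
        steps, ref, stack = reference
        anchored = ps.fit_pixels_anchored(stack, steps, 2, ref)
        np.testing.assert_allclose(anchored.phase, 0.0, atol=1e-9)
        assert anchored.anchored

    def test_wrap_free_differential_phase(self):
        """A +0.3 rad shift on a reference phase of 3.0 rad reads 0.3, not -5.98."""
        rng = np.random.default_rng(4)
        steps = ps.StepVector(np.sort(rng.uniform(0, 110, 10)), period_W=120.0)
        shape = (2, 2)
        ref_truth = ps.HarmonicField(
            a0=np.full(shape, 100.0), amp=np.full((1, *shape), 30.0),
            phase=np.full((1, *shape), 3.0), linear=None, n_H=1,
        )
        ref = ps.fit_pixels(ps.evaluate_model(ref_truth, steps), steps, 1)
        samp_truth = ps.HarmonicField(
            a0=ref_truth.a0, amp=ref_truth.amp,
            phase=wrap(ref_truth.phase + 0.3), linear=None, n_H=1,
        )
        anchored = ps.fit_pixels_anchored(
            ps.evaluate_model(samp_truth, steps), steps, 1, ref
        )
        np.testing.assert_allclose(anchored.phase[0], 0.3, atol=1e-9)

    def test_matches_unanchored_fit_plus_wrapped_subtraction(self, reference):
        steps, ref, _ = reference
        rng = np.random.default_rng(5)
        sample = random_field((4, 5), 2, rng)
        stack = ps.evaluate_model(sample, steps)
        anchored = ps.fit_pixels_anchored(stack, steps, 2, ref)
        plain = ps.fit_pixels(stack, steps, 2)
        np.testing.assert_allclose(
            wrap(anchored.phase - (plain.phase - ref.phase)), 0.0, atol=1e-9
        )
        np.testing.assert_allclose(anchored.amp, plain.amp, rtol=1e-9)

    def test_zero_anchor_reduces_to_plain_fit(self, reference):
        steps, ref, stack = reference
        zero_ref = ps.HarmonicField(
            a0=ref.a0, amp=ref.amp, phase=np.zeros_like(ref.phase),
            linear=None, n_H=2,
        )
        anchored = ps.fit_pixels_anchored(stack, steps, 2, zero_ref)
        plain = ps.fit_pixels(stack, steps, 2)
        np.testing.assert_allclose(anchored.phase, plain.phase, atol=1e-10)
        np.testing.assert_allclose(anchored.amp, plain.amp, rtol=1e-12)

    def test_shape_mismatch_rejected(self, reference):
        steps, ref, _ = reference
        bad = ps.FringeStack(np.full((10, 3, 3), 10.0))
        with pytest.raises(ValueError, match="shape"):
            ps.fit_pixels_anchored(bad, steps, 2, ref)


class TestEvaluateModel:
    def test_offset_only_field_is_constant(self):
        steps = ps.StepVector(np.arange(5) * 20.0, period_W=120.0)
        field = ps.HarmonicField(
            a0=np.full((2, 2), 7.0), amp=np.zeros((1, 2, 2)),
            phase=np.zeros((1, 2, 2)), linear=None, n_H=1,
        )
        stack = ps.evaluate_model(field, steps)
        np.testing.assert_allclose(stack.intensities, 7.0)

    def test_phase_translation_identity(self):
        """Shifting all steps by d equals advancing phi_n by 2 pi n d / W."""
        rng = np.random.default_rng(9)
        steps = ps.StepVector(np.sort(rng.uniform(0, 100, 9)), period_W=120.0)
        field = random_field((3, 3), 3, rng)
        delta = 13.7
        shifted = ps.evaluate_model(field, steps.shifted(delta))
        advanced = ps.HarmonicField(
            a0=field.a0, amp=field.amp,
            phase=field.phase
            + (2 * np.pi * np.arange(1, 4) * delta / 120.0)[:, None, None],
            linear=None, n_H=3,
        )
        np.testing.assert_allclose(
            shifted.intensities, ps.evaluate_model(advanced, steps).intensities,
            rtol=1e-10, atol=1e-8,
        )

    def test_fit_evaluate_roundtrip(self):
        rng = np.random.default_rng(10)
        steps = ps.StepVector(np.sort(rng.uniform(0, 110, 10)), period_W=120.0)
        field = random_field((3, 4), 2, rng)
        stack = ps.evaluate_model(field, steps)
        refit = ps.fit_pixels(stack, steps, 2)
        again = ps.evaluate_model(refit, steps)
        assert np.abs(again.intensities - stack.intensities).max() < 1e-9 * field.a0.max()

    def test_linear_and_polar_reconstructions_agree(self):
        rng = np.random.default_rng(11)
        steps = ps.StepVector(np.sort(rng.uniform(0, 110, 10)), period_W=120.0)
        stack = ps.FringeStack(rng.uniform(50, 150, (10, 3, 3)))
        fitted = ps.fit_pixels(stack, steps, 2)
        basis = ps.build_basis(steps, 2)
        from_linear = np.einsum("gp,ijp->gij", basis, fitted.linear)
        np.testing.assert_allclose(
            from_linear, predicted_intensities(fitted, steps), rtol=1e-10, atol=1e-9
        )


class TestGaugeCovariance:
    def test_uniform_translation_moves_only_phases(self):
        rng = np.random.default_rng(12)
        steps = ps.StepVector(np.sort(rng.uniform(0, 110, 10)), period_W=120.0)
        stack = ps.FringeStack(rng.uniform(50, 150, (10, 4, 4)))
        delta = 7.31
        base = ps.fit_pixels(stack, steps, 3)
        shifted = ps.fit_pixels(stack, steps.shifted(-delta), 3)
        np.testing.assert_allclose(shifted.a0, base.a0, rtol=1e-9)
        np.testing.assert_allclose(shifted.amp, base.amp, rtol=1e-8)
        expected_advance = (2 * np.pi * np.arange(1, 4) * delta / 120.0)[:, None, None]
        np.testing.assert_allclose(
            wrap(shifted.phase - base.phase - expected_advance), 0.0, atol=1e-8
        )
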