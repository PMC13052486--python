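"""Dynamic-speckle simulator: statistics, limits, phantom and motion physics."""

import numpy as np
import pytest

from lsci.core import InvalidInputError
from lsci.simulate import (
    STATIC_TAU_C,
    MotionEvent,
    SubstepError,
    channel_band_rois,
    generate_static_speckle,
    global_contrast,
    inject_motion,
    make_flow_phantom,
    phantom_rois,
    render_sequence,
    speckle_contrast_model,
)
from lsci.contrast import series_roi_stats
from tests.conftest import measured_speckle_diameter, uniform_tau_spec


class TestStaticSpeckle:
    def test_fully_developed_contrast_near_unity(self):
        """Polarized fully developed speckle has global std/mean ~ 1."""
        ks = [
            global_contrast(generate_static_speckle((256, 256), 4.0, 1.0, seed=s))
            for s in range(5)
        ]
        assert 0.85 <= np.mean(ks) <= 1.05

    def test_partial_coherence_caps_contrast_at_sqrt_beta(self):
        """beta = 0.25 gives global contrast ~ sqrt(0.25) = 0.5."""
        ks = [
            global_contrast(generate_static_speckle((256, 256), 4.0, 0.25, seed=s))
            for s in range(5)
        ]
        assert abs(np.mean(ks) - 0.5) < 0.1

    def test_fixed_seed_is_bit_reproducible(self):
        a = generate_static_speckle((64, 64), 4.0, seed=7)
        b = generate_static_speckle((64, 64), 4.0, seed=7)
        assert np.array_equal(a.pixels, b.pixels)
        c = generate_static_speckle((64, 64), 4.0, seed=8)
        assert not np.array_equal(a.pixels, c.pixels)

    @pytest.mark.parametrize("size", [3.0, 4.0, 6.0])
    def test_speckle_size_matches_autocorrelation_width(self, size):
        """Intensity autocovariance width tracks the requested diameter within 20%."""
        fr = generate_static_speckle((256, 256), size, seed=11)
        measured = measured_speckle_diameter(fr.pixels)
        assert abs(measured - size) / size <= 0.20

    def test_intensity_nonnegative(self):
        fr = generate_static_speckle((64, 64), 4.0, 0.5, seed=3)
        assert np.all(fr.pixels >= 0)

    @pytest.mark.parametrize("bad", [(0, 64), (64, -1)])
    def test_invalid_grid_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            generate_static_speckle(bad, 4.0)

    def test_invalid_speckle_size_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_static_speckle((64, 64), 0.0)


class TestRenderSequence:
    def test_determinism_bit_identical(self):
        spec = uniform_tau_spec((64, 64), 1.0, seed=5, n_frames=3)
        a = render_sequence(spec)
        b = render_sequence(uniform_tau_spec((64, 64), 1.0, seed=5, n_frames=3))
        assert np.array_equal(a.pixels, b.pixels)

    def test_slow_dynamics_reduce_to_static_limit(self):
        """tau_c = 100*T leaves the exposure-averaged contrast within 10% of static."""
        static_k = global_contrast(generate_static_speckle((128, 128), 4.0, seed=2))
        spec = uniform_tau_spec((128, 128), 500.0, seed=2)  # T = 5 ms
        k = global_contrast(render_sequence(spec).pixels[0])
        assert abs(k - static_k) / static_k < 0.10

    def test_fast_dynamics_blur_contrast(self):
        """tau_c = 0.01*T wipes out most of the static contrast."""
        static_k = global_contrast(generate_static_speckle((64, 64), 4.0, seed=2))
        spec = uniform_tau_spec((64, 64), 0.05, seed=2)
        k = global_contrast(render_sequence(spec).pixels[0])
        assert k < 0.2 * static_k

    def test_contrast_monotone_in_tau_c(self):
        """Shorter correlation time (faster flow) gives lower contrast."""
        ks = []
        for tau in (0.5, 5.0, 50.0):
            spec = uniform_tau_spec((64, 64), tau, seed=9)
            ks.append(global_contrast(render_sequence(spec).pixels[0]))
        assert ks[0] < ks[1] < ks[2]

    def test_insufficient_substeps_refused_with_requirement(self):
        spec = uniform_tau_spec((32, 32), 0.5, seed=1)  # requires 100 sub-steps
        with pytest.raises(SubstepError) as ei:
            render_sequence(spec, n_substeps=30)
        assert ei.value.required == 100
        render_sequence(spec, n_substeps=100)  # exactly the requirement is fine

    def test_static_field_is_frozen_across_frames(self):
        spec = uniform_tau_spec((32, 32), STATIC_TAU_C, seed=4, n_frames=3)
        stack = render_sequence(spec)
        assert np.array_equal(stack.pixels[0], stack.pixels[2])

    def test_measured_contrast_matches_closed_form(self):
        """Exposure-integrated contrast tracks K(T, tau_c, beta) at tau_c = T."""
        spec = uniform_tau_spec((128, 128), 5.0, seed=6)
        k = global_contrast(render_sequence(spec).pixels[0])
        model = speckle_contrast_model(5.0, 5.0)
        assert abs(k - model) / model < 0.15


class TestFlowPhantom:
    def test_no_flow_channel_indistinguishable_from_background(self):
        spec = make_flow_phantom((96, 96), 32, STATIC_TAU_C, seed=3, n_frames=1)
        stack = render_sequence(spec)
        ch, bg = channel_band_rois(spec, 32, 64)
        trace_ch = series_roi_stats(stack, ch, max_frames=1)
        trace_bg = series_roi_stats(stack, bg, max_frames=1)
        a, b = trace_ch.per_frame_mean_k[0], trace_bg.per_frame_mean_k[0]
        assert abs(a - b) / b < 0.10

    def test_flow_channel_has_lower_contrast_than_background(self):
        spec = make_flow_phantom((96, 96), 32, 0.5, seed=3, n_frames=5)
        stack = render_sequence(spec)
        ch, bg = phantom_rois(spec)
        t_ch = series_roi_stats(stack, ch, max_frames=5).per_frame_mean_k
        t_bg = series_roi_stats(stack, bg, max_frames=5).per_frame_mean_k
        assert t_ch.max() < t_bg.min()  # no overlap over the traces

    def test_faster_channel_has_lower_contrast(self):
        """Reproduces the flow ordering K(no flow) > K(slow) > K(fast)."""
        means = {}
        for label, tau in [("slow", 2.0), ("fast", 0.1)]:
            spec = make_flow_phantom((96, 96), 32, tau, seed=5, n_frames=2)
            ch, _ = phantom_rois(spec)
            means[label] = series_roi_stats(
                render_sequence(spec), ch, max_frames=2
            ).per_frame_mean_k.mean()
        spec0 = make_flow_phantom((96, 96), 32, STATIC_TAU_C, seed=5, n_frames=2)
        ch0, _ = channel_band_rois(spec0, 32, 64)
        means["no_flow"] = series_roi_stats(
            render_sequence(spec0), ch0, max_frames=2
        ).per_frame_mean_k.mean()
        assert means["no_flow"] > means["slow"] > means["fast"]

    def test_channel_wider_than_grid_rejected(self):
        with pytest.raises(InvalidInputError, match="exceeds"):
            make_flow_phantom((64, 64), 80, 1.0)


class TestInjectMotion:
    def test_no_events_is_identity(self):
        spec = uniform_tau_spec((32, 32), STATIC_TAU_C, seed=1, n_frames=2)
        stack = render_sequence(spec)
        assert inject_motion(stack, [], seed=0) is stack

    def test_zero_displacement_leaves_frames_unchanged(self):
        spec = uniform_tau_spec((32, 32), STATIC_TAU_C, seed=1, n_frames=2)
        stack = render_sequence(spec)
        out = inject_motion(stack, [MotionEvent(0, (0.0, 0.0))], seed=0)
        np.testing.assert_allclose(out.pixels, stack.pixels, rtol=1e-12)

    def test_unaffected_frames_stay_bit_identical(self):
        spec = uniform_tau_spec((64, 64), 1.0, seed=8, n_frames=3)
        stack = render_sequence(spec)
        out = inject_motion(stack, [MotionEvent(1, (0.0, 10.0))], seed=0)
        assert np.array_equal(out.pixels[0], stack.pixels[0])
        assert np.array_equal(out.pixels[2], stack.pixels[2])
        assert not np.array_equal(out.pixels[1], stack.pixels[1])

    def test_motion_reduces_contrast_of_static_frame(self):
        spec = uniform_tau_spec((128, 128), STATIC_TAU_C, seed=8, n_frames=1)
        stack = render_sequence(spec)
        out = inject_motion(stack, [MotionEvent(0, (0.0, 10.0))], seed=0)
        assert global_contrast(out.pixels[0]) < global_contrast(stack.pixels[0])

    def test_blur_magnitude_matches_1d_uniform_motion_oracle(self):
        """Blurred contrast agrees with the triangular-weighted autocovariance
        integral computed from the clean frame itself."""
        spec = uniform_tau_spec((256, 256), STATIC_TAU_C, seed=8, n_frames=1)
        clean = render_sequence(spec).pixels[0]
        L = 20.0
        blurred = inject_motion(
            render_sequence(spec), [MotionEvent(0, (0.0, L))], seed=0
        ).pixels[0]

        # oracle: averaging N uniformly spaced shifted copies gives
        # K^2 = [N*Cov(0) + 2*sum_k (N-k)*Cov(k*L/N)] / (N^2 * mean^2), with
        # Cov the measured circular autocovariance of the clean frame along
        # the motion axis (independent of the simulator's blur code path)
        n_sub = 20
        c = clean - clean.mean()
        cov = np.fft.ifft2(np.abs(np.fft.fft2(c)) ** 2).real / clean.size
        lag_px = (np.arange(1, n_sub) * L / n_sub).round().astype(int)
        cov_prof = cov[0, lag_px]
        k2 = (
            n_sub * cov[0, 0] + 2.0 * np.sum((n_sub - np.arange(1, n_sub)) * cov_prof)
        ) / (n_sub**2 * clean.mean() ** 2)
        oracle = np.sqrt(k2)
        measured = global_contrast(blurred)
        assert abs(measured - oracle) / oracle < 0.15

    def test_event_outside_stack_rejected(self):
        spec = uniform_tau_spec((32, 32), STATIC_TAU_C, seed=1, n_frames=2)
        stack = render_sequence(spec)
        with pytest.raises(InvalidInputError, match="outside"):
            inject_motion(stack, [MotionEvent(5, (0.0, 1.0))], seed=0)

    def test_intensity_domain_fallback_without_spec(self):
        from lsci.core import SpeckleStack

        px = render_sequence(uniform_tau_spec((64, 64), STATIC_TAU_C, seed=2)).pixels
        bare = SpeckleStack(pixels=px.copy())
        out = inject_motion(bare, [MotionEvent(0, (0.0, 8.0))], seed=0)
        assert global_contrast(out.pixels[0]) < global_contrast(px[0])
        assert np.all(out.pixels >= 0)


class TestClosedFormModel:
    def test_limits(self):
        assert speckle_contrast_model(5.0, STATIC_TAU_C) == 1.0
        assert speckle_contrast_model(5.0, STATIC_TAU_C, 0.25) == 0.5
        # tau_c >> T approaches sqrt(beta)
        assert speckle_contrast_model(5.0, 5e6) == pytest.approx(1.0, abs=1e-3)
        # tau_c << T approaches sqrt(tau_c/T)
        assert speckle_contrast_model(5.0, 5e-4) == pytest.approx(1e-2, rel=1e-3)

    def test_monotone_in_tau_c(self):
        taus = np.logspace(-3, 3, 25)
        ks = [speckle_contrast_model(5.0, t) for t in taus]
        assert np.all(np.diff(ks) > 0)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidInputError):
            speckle_contrast_model(0.0, 1.0)
        with pytest.raises(InvalidInputError):
            speckle_contrast_model(5.0, -1.0)
        with pytest.raises(InvalidInputError):
            speckle_contrast_model(5.0, 1.0, 1.5)
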