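"""Template matching, sub-pixel refinement and trajectory tracking."""

import numpy as np
import pytest

from spheromech import (
    ConstantWindowError,
    FrameSpec,
    TipTemplate,
    TrackingLostError,
    ValidationError,
    compute_deflections,
    make_tip_template,
    match_template,
    refine_subpixel,
    render_tip_frame,
    track_tips,
)
from spheromech import presets
from spheromech.synth_mech import simulate_compression_experiment


def _embed(template: np.ndarray, shape, anchor_at, background=0.0):
    """Place a template so its anchor (center) lands at ``anchor_at``."""
    frame = np.full(shape, background)
    half = template.shape[0] // 2
    r, c = anchor_at
    frame[r - half:r + half + 1, c - half:c + half + 1] += template
    return frame


def _ssd_search(frame, template):
    """Brute-force sum-of-squared-differences matcher (independent oracle)."""
    th, tw = template.shape
    best, best_pos = np.inf, None
    for r in range(frame.shape[0] - th + 1):
        for c in range(frame.shape[1] - tw + 1):
            patch = frame[r:r + th, c:c + tw]
            ssd = np.sum((patch - patch.mean() - (template - template.mean())) ** 2)
            if ssd < best:
                best, best_pos = ssd, (r + th // 2, c + tw // 2)
    return best_pos


class TestMatchTemplate:
    def test_exact_embed_scores_one(self):
        template = make_tip_template()
        frame = _embed(template, (120, 120), (40, 60))
        (r, c), score, _, _ = match_template(frame, TipTemplate(template))
        assert (r, c) == (40, 60)
        assert score == pytest.approx(1.0, abs=1e-10)

    def test_noisy_embed_within_one_pixel_of_ssd_oracle(self, rng):
        template = make_tip_template()
        frame = _embed(template, (90, 90), (44, 37))
        frame = frame + rng.normal(0, 0.05 * np.ptp(frame), frame.shape)
        (r, c), _, _, _ = match_template(frame, TipTemplate(template))
        assert abs(r - 44) <= 1 and abs(c - 37) <= 1
        or_, oc = _ssd_search(frame, template)
        assert abs(r - or_) <= 1 and abs(c - oc) <= 1

    def test_tie_breaks_to_smallest_row(self):
        template = np.zeros((5, 5))
        template[2, 2] = 1.0
        frame = np.zeros((40, 20))
        frame[10, 8] = 1.0  # identical embeds at rows 10 and 25
        frame[25, 8] = 1.0
        (r, c), score, _, _ = match_template(frame, TipTemplate(template))
        assert (r, c) == (10, 8)

    def test_constant_window_raises(self):
        template = make_tip_template()
        with pytest.raises(ConstantWindowError):
            match_template(np.zeros((60, 60)), TipTemplate(template))


class TestRefineSubpixel:
    def test_symmetric_peak_gives_zero_offset(self):
        surface = np.array([[0, 0, 0], [0.5, 1.0, 0.5], [0, 0, 0]]).T
        assert refine_subpixel(surface, (1, 1)) == (0.0, 0.0)

    def test_flat_neighbors_give_zero_offset(self):
        surface = np.ones((3, 3))
        assert refine_subpixel(surface, (1, 1)) == (0.0, 0.0)

    def test_border_peak_returns_integer(self):
        surface = np.random.default_rng(0).random((5, 5))
        assert refine_subpixel(surface, (0, 2)) == (0.0, 0.0)

    def test_recovers_known_subpixel_shift(self):
        """Frames rendered at +0.3 px recover offset 0.3 ± 0.1 (noiseless)."""
        template = make_tip_template()
        frame_spec = FrameSpec(height_px=80, width_px=80, background=0.0)
        frame = render_tip_frame([(40.3, 40.0)], template, frame_spec)
        (r, c), _, surface, origin = match_template(frame, TipTemplate(template))
        dr, dc = refine_subpixel(surface, (r - origin[0], c - origin[1]))
        assert r + dr == pytest.approx(40.3, abs=0.1)
        assert c + dc == pytest.approx(40.0, abs=0.1)


class TestTrackTips:
    def test_noiseless_reference_tracks_to_ground_truth(self):
        ref, _, truth = simulate_compression_experiment(
            presets.ACTUATION, presets.CANTILEVER, presets.DAY5_SPHEROID,
            noise_sd=0.0, seed=0)
        traj = track_tips(ref, make_tip_template(), truth.reference_positions_px[0])
        err = traj.positions_px - truth.reference_positions_px
        assert np.sqrt(np.mean(err**2)) < 0.05

    def test_identical_frames_give_constant_trajectory(self):
        template = make_tip_template()
        spec = FrameSpec(height_px=120, width_px=80, background=0.0)
        frame = render_tip_frame([(30.0, 40.0), (90.0, 40.0)], template, spec)
        frames = np.stack([frame] * 5)
        traj = track_tips(frames, template, [[30, 40], [90, 40]])
        assert np.ptp(traj.positions_px, axis=0).max() == 0.0

    def test_small_search_radius_loses_track(self):
        ref, _, truth = simulate_compression_experiment(
            presets.ACTUATION, presets.CANTILEVER, presets.DAY5_SPHEROID,
            noise_sd=0.0, seed=0)
        with pytest.raises(TrackingLostError):
            track_tips(ref, make_tip_template(), truth.reference_positions_px[0],
                       search_radius=1)

    def test_translation_equivariance_integer_shift(self):
        """Shifting every frame by (Δr, Δc) shifts every position exactly."""
        ref, _, truth = simulate_compression_experiment(
            presets.ACTUATION, presets.CANTILEVER, presets.DAY5_SPHEROID,
            noise_sd=0.02, seed=4)
        shift = (7, -3)
        shifted = np.roll(ref, shift, axis=(1, 2))
        base = track_tips(ref, make_tip_template(), truth.reference_positions_px[0])
        moved = track_tips(shifted, make_tip_template(),
                           truth.reference_positions_px[0] + np.asarray(shift))
        np.testing.assert_allclose(
            moved.positions_px - base.positions_px,
            np.broadcast_to(np.asarray(shift, float), base.positions_px.shape),
            atol=1e-9)


class TestComputeDeflections:
    def test_identical_runs_give_zero_deflection(self):
        ref, _, truth = simulate_compression_experiment(
            presets.ACTUATION, presets.CANTILEVER, presets.DAY5_SPHEROID,
            noise_sd=0.0, seed=0)
        traj = track_tips(ref, make_tip_template(), truth.reference_positions_px[0])
        series = compute_deflections(traj, traj, 2.0)
        np.testing.assert_array_equal(series.deflections_um, 0.0)

    def test_swapping_arguments_negates_deflections(self, day20_result_noisy):
        loaded, reference = day20_result_noisy.trajectories
        fwd = compute_deflections(loaded, reference, 2.0)
        rev = compute_deflections(reference, loaded, 2.0)
        np.testing.assert_allclose(fwd.deflections_um, -rev.deflections_um)

    def test_day20_deflections_match_ground_truth(self, day20_result_noisy):
        """Tracked per-tip deflections reproduce the simulated d to <0.1 μm."""
        truth = day20_result_noisy.truth
        loaded, reference = day20_result_noisy.trajectories
        series = compute_deflections(loaded, reference, truth.pixel_pitch_um)
        # top tip deflects upward (negative rows), bottom downward
        measured = np.column_stack([-series.deflections_um[:, 0],
                                    series.deflections_um[:, 1]])
        err = measured - truth.deflection_um[:, None]
        assert np.sqrt(np.mean(err**2)) < 0.1
        assert np.abs(err).max() < 0.25

    def test_step_count_mismatch_raises(self, day20_result_noisy):
        import dataclasses
        loaded, reference = day20_result_noisy.trajectories
        short = dataclasses.replace(
            reference, positions_px=reference.positions_px[:-1],
            scores=reference.scores[:-1])
        with pytest.raises(ValidationError, match="mismatch"):
            compute_deflections(loaded, short, 2.0)
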