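"""Representations: resampling, normalization, cycles, GEI/SEI averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitkit import body25, gaitsim, represent as rep
from gaitkit.sequences import PoseSequence, SilhouetteSequence


def _blank_masks(n, h=40, w=40, fps=10.0):
    return SilhouetteSequence(np.zeros((n, h, w), dtype=bool), fps=fps)


class TestResampleFramerate:
    def test_integer_ratio_takes_every_third_frame(self):
        src = SilhouetteSequence(np.zeros((90, 8, 8), bool), fps=30)
        src.masks[::3, 0, 0] = True  # tag the frames that must survive
        out = rep.resample_framerate(src, 10)
        assert len(out) == 30
        assert out.masks[:, 0, 0].all()

    def test_matching_rate_is_identity(self):
        src = _blank_masks(17)
        assert rep.resample_framerate(src, 10) is src

    def test_fractional_ratio_uses_rounded_indices(self):
        src = SilhouetteSequence(np.zeros((100, 8, 8), bool), fps=25)
        out = rep.resample_framerate(src, 10)
        # oracle: k -> round(k * 25/10), while inside the sequence
        expected = [int(np.floor(k * 2.5 + 0.5)) for k in range(45)]
        expected = [i for i in expected if i <= 99]
        assert len(out) == len(expected) == 40

    def test_upsampling_refused(self):
        with pytest.raises(ValueError):
            rep.resample_framerate(_blank_masks(10, fps=10.0), 30)


class TestCanonicalizeDirection:
    def test_left_to_right_is_identity(self, silhouette_from_walker):
        out = rep.canonicalize_direction(silhouette_from_walker,
                                         "left_to_right")
        assert out is silhouette_from_walker

    def test_double_flip_is_identity(self, walker_sequence):
        poses = walker_sequence.poses
        flipped = rep.canonicalize_direction(poses, "right_to_left")
        back = rep.canonicalize_direction(flipped, "right_to_left")
        np.testing.assert_allclose(back.keypoints, poses.keypoints, atol=1e-4)

    def test_flip_swaps_wrist_indices(self, walker_sequence):
        poses = walker_sequence.poses
        width = poses.frame_shape[1]
        flipped = rep.canonicalize_direction(poses, "right_to_left")
        np.testing.assert_allclose(
            flipped.keypoints[:, body25.R_WRIST, 0],
            (width - 1) - poses.keypoints[:, body25.L_WRIST, 0], atol=1e-4)


class TestNormalizeSilhouette:
    def test_full_frame_square_becomes_all_ones(self):
        out = rep.normalize_silhouette(np.ones((50, 50), bool))
        assert out.shape == (224, 224)
        assert out.all()

    def test_tall_rectangle_scales_and_centres(self):
        mask = np.zeros((200, 200), bool)
        mask[50:150, 30:80] = True  # 100 x 50
        out = rep.normalize_silhouette(mask)
        rows = np.where(out.any(axis=1))[0]
        cols = np.where(out.any(axis=0))[0]
        assert rows[0] == 0 and rows[-1] == 223
        assert cols[-1] - cols[0] + 1 == 112
        centroid = out.any(axis=0).nonzero()[0].mean()
        assert abs(centroid - 112) <= 1.0

    def test_single_pixel_becomes_full_height_bar(self):
        mask = np.zeros((30, 30), bool)
        mask[10, 10] = True
        out = rep.normalize_silhouette(mask)
        rows = np.where(out.any(axis=1))[0]
        assert rows[0] == 0 and rows[-1] == 223

    def test_empty_mask_raises(self):
        with pytest.raises(rep.EmptyMaskError):
            rep.normalize_silhouette(np.zeros((10, 10), bool))


class TestDetectGaitCycles:
    @pytest.mark.parametrize("period", [14, 20])
    def test_recovers_known_walker_period(self, period):
        cfg = gaitsim.WalkerConfig(gait_type="normal",
                                   frames_per_cycle=period, n_cycles=3,
                                   seed=2)
        seq = gaitsim.generate_walker_sequence(cfg, render_rgb=False)
        cycles = rep.detect_gait_cycles(SilhouetteSequence(seq.truth_masks,
                                                           fps=10))
        assert cycles
        for c in cycles:
            assert abs((c.end_frame - c.start_frame) - period) <= 1

    def test_constant_width_gives_no_cycle(self):
        masks = np.zeros((40, 30, 30), bool)
        masks[:, 10:20, 10:20] = True
        assert rep.detect_gait_cycles(SilhouetteSequence(masks, fps=10)) == []

    def test_cycles_are_ordered_and_non_overlapping(self,
                                                    silhouette_from_walker):
        cycles = rep.detect_gait_cycles(silhouette_from_walker)
        for a, b in zip(cycles, cycles[1:]):
            assert a.end_frame <= b.start_frame


class TestEnergyImage:
    def test_mean_of_identical_frames_is_the_frame(self):
        frame = np.zeros((224, 224), np.float32)
        frame[40:180, 100:130] = 1.0
        out = rep.compute_energy_image([frame] * 5, "GEI", "whole_sequence")
        np.testing.assert_array_equal(out.pixels, frame)

    def test_two_term_mean_is_half(self):
        ones = np.ones((224, 224), np.float32)
        zeros = np.zeros((224, 224), np.float32)
        out = rep.compute_energy_image([ones, zeros], "GEI", "per_cycle")
        np.testing.assert_array_equal(out.pixels, np.full((224, 224), 0.5))

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=32),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_mean(self, n, seed):
        rng = np.random.default_rng(seed)
        stack = (rng.random((n, 224, 224)) < 0.5).astype(np.float32)
        out = rep.compute_energy_image(stack, "GEI", "whole_sequence")
        brute = np.zeros((224, 224), dtype=np.float64)
        for frame in stack:
            brute += frame
        brute /= n
        assert np.abs(out.pixels - brute).max() <= 1e-6

    def test_invariant_to_frame_order(self):
        rng = np.random.default_rng(1)
        stack = (rng.random((7, 224, 224)) < 0.4).astype(np.float32)
        a = rep.compute_energy_image(stack, "GEI", "whole_sequence")
        b = rep.compute_energy_image(stack[::-1], "GEI", "whole_sequence")
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_whole_sequence_equals_weighted_mean_of_tiling_cycles(self):
        rng = np.random.default_rng(2)
        stack = (rng.random((12, 224, 224)) < 0.5).astype(np.float32)
        whole = rep.compute_energy_image(stack, "GEI", "whole_sequence")
        c1 = rep.compute_energy_image(stack[:5], "GEI", "per_cycle")
        c2 = rep.compute_energy_image(stack[5:], "GEI", "per_cycle")
        weighted = (5 * c1.pixels + 7 * c2.pixels) / 12
        np.testing.assert_allclose(whole.pixels, weighted, atol=1e-6)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            rep.compute_energy_image([], "GEI", "whole_sequence")


class TestRasterizeSkeleton:
    def test_two_connected_keypoints_draw_a_thick_bar(self):
        kp = np.zeros((25, 3), np.float32)
        kp[body25.NECK] = (5, 10, 1.0)
        kp[body25.NOSE] = (25, 10, 1.0)
        img = rep.rasterize_skeleton(kp, (30, 40))
        assert img[10, 5:26].all()
        col = img[:, 15]
        assert 2 <= col.sum() <= 5  # documented thickness ~3 px
        assert img.sum() == img[8:13, 3:28].sum()  # nothing drawn elsewhere

    def test_low_confidence_endpoint_suppresses_the_limb(self):
        kp = np.zeros((25, 3), np.float32)
        kp[body25.NECK] = (5, 10, 1.0)
        kp[body25.NOSE] = (25, 10, 0.05)
        kp[body25.MID_HIP] = (5, 25, 1.0)
        img = rep.rasterize_skeleton(kp, (40, 40))
        assert not img[10, 15]          # neck-nose absent
        assert img[18, 5]               # neck-midhip present

    def test_all_low_confidence_frame_raises_skip_signal(self):
        kp = np.zeros((25, 3), np.float32)
        with pytest.raises(rep.AllLowConfidenceError):
            rep.rasterize_skeleton(kp, (30, 30))

    def test_walker_pose_draws_every_confident_limb_pair(self,
                                                         walker_sequence):
        kp = walker_sequence.poses.keypoints[0]
        n = rep.count_drawable_limbs(kp)
        ok = kp[:, 2] > rep.CONFIDENCE_THRESHOLD
        expected = sum(1 for a, b in body25.LIMB_PAIRS if ok[a] and ok[b])
        assert n == expected == 14


def test_sei_runs_through_the_gei_averaging_path(walker_sequence):
    """SEI = the GEI pipeline applied to rasterized skeleton frames."""
    poses = walker_sequence.poses
    skeletons = [rep.normalize_silhouette(
        rep.rasterize_skeleton(kp, poses.frame_shape))
        for kp in poses.keypoints]
    by_hand = rep.compute_energy_image(skeletons, "SEI", "whole_sequence")
    [via_pipeline] = rep.sequence_representations(poses, kind="SEI")
    np.testing.assert_array_equal(by_hand.pixels, via_pipeline.pixels)
    assert via_pipeline.kind == "SEI"
    assert via_pipeline.pixels.min() >= 0.0
    assert via_pipeline.pixels.max() <= 1.0
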