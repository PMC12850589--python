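"""Preparation steps: smoothing, cropping, normalization, patch arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angio4d.core import Volume4D
from angio4d.preprocess import (
    crop_volume,
    extract_3slice_windows,
    extract_volume_patches,
    extract_xy_slices,
    frames_from_spokes,
    plan_axis_origins,
    plan_volume_patch_origins,
    split_cohort,
    stitch_volume_patches,
    temporal_moving_average,
    temporal_resample,
    tmip,
    zscore_normalize,
)


def vol(data):
    return Volume4D(np.asarray(data, dtype=np.float32))


class TestTemporalMovingAverage:
    def test_constant_unchanged(self):
        v = vol(np.full((4, 4, 2, 8), 3.0))
        np.testing.assert_allclose(temporal_moving_average(v, 3).data, 3.0, rtol=1e-6)

    def test_interior_mean_and_truncated_boundary(self):
        series = np.array([1.0, 2.0, 3.0, 4.0])
        v = vol(series.reshape(1, 1, 1, 4))
        out = temporal_moving_average(v, 3).data[0, 0, 0]
        np.testing.assert_allclose(out, [1.5, 2.0, 3.0, 3.5], rtol=1e-6)

    def test_window_one_is_identity(self, rng):
        v = vol(rng.normal(size=(3, 3, 2, 6)))
        np.testing.assert_array_equal(temporal_moving_average(v, 1).data, v.data)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            temporal_moving_average(vol(np.zeros((2, 2, 2, 4))), 2)


class TestCrop:
    def test_published_acquisition_dims(self):
        v = vol(np.zeros((256, 256, 36, 25), dtype=np.float32))
        out = crop_volume(v, (192, 192, 32, 24))
        assert out.shape == (192, 192, 32, 24)

    def test_identity_when_equal(self, rng):
        v = vol(rng.normal(size=(16, 16, 4, 6)))
        np.testing.assert_array_equal(crop_volume(v, (16, 16, 4, 6)).data, v.data)

    def test_center_crop_and_leading_frames(self):
        data = np.zeros((8, 8, 4, 4), dtype=np.float32)
        data[2:6, 2:6, 1:3, :2] = 1.0
        out = crop_volume(vol(data), (8, 8, 2, 2))
        assert out.data.sum() == data[:, :, 1:3, :2].sum()

    def test_non_divisible_target_rejected(self):
        with pytest.raises(ValueError):
            crop_volume(vol(np.zeros((16, 16, 4, 4))), (12, 16, 4, 4))

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError):
            crop_volume(vol(np.zeros((16, 16, 4, 4))), (24, 16, 4, 4))


class TestZScore:
    def test_output_standardized(self, rng):
        out = zscore_normalize(vol(rng.normal(5, 3, size=(8, 8, 4, 6))))
        assert abs(out.data.mean()) < 1e-5
        assert out.data.std() == pytest.approx(1.0, abs=1e-5)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(6, 6, 3, 5)).astype(np.float32)
        a = zscore_normalize(vol(x)).data
        b = zscore_normalize(vol(2.5 * x + 7.0)).data
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="sub-x"):
            zscore_normalize(vol(np.ones((4, 4, 2, 3))), subject_id="sub-x")


class TestTmip:
    def test_single_frame_identity(self, rng):
        v = vol(rng.normal(size=(5, 5, 3, 1)))
        np.testing.assert_array_equal(tmip(v), v.data[..., 0])

    def test_elementwise_max(self, rng):
        v = vol(rng.normal(size=(5, 5, 3, 2)))
        np.testing.assert_array_equal(tmip(v), np.maximum(v.data[..., 0], v.data[..., 1]))

    def test_smoothing_cannot_raise_tmip(self, rng):
        v = vol(rng.normal(size=(6, 6, 2, 10)))
        assert (tmip(temporal_moving_average(v, 3)) <= tmip(v) + 1e-6).all()


class TestPatchPlans:
    def test_slice_patch_count_cohort(self):
        # 28 subjects x 32 slices = 896 slice patches
        volumes = {f"s{i}": np.zeros((4, 4, 32)) for i in range(28)}
        assert len(extract_xy_slices(volumes)) == 896

    def test_three_slice_windows_count(self):
        # 896 concatenated slices -> 894 stride-1 windows
        volumes = {f"s{i}": np.zeros((4, 4, 32, 2)) for i in range(28)}
        ps = extract_3slice_windows(volumes, mode="train")
        assert len(ps) == 894

    def test_three_slices_single_window(self):
        ps = extract_3slice_windows({"a": np.zeros((4, 4, 3, 2))}, mode="train")
        assert len(ps) == 1

    def test_inference_windows_one_per_slice(self):
        ps = extract_3slice_windows({"a": np.zeros((4, 4, 32, 2))}, mode="inference")
        assert len(ps) == 32
        # replicate padding: the first window's outer slice equals its center
        first = ps.patches[0]
        np.testing.assert_array_equal(first[:, :, 0], first[:, :, 1])

    def test_volume_patch_count_no_context(self):
        origins = plan_volume_patch_origins((192, 192, 32), (64, 64, 8), (32, 32, 4))
        assert 28 * len(origins) == 4900

    def test_volume_patch_count_with_context(self):
        origins = plan_volume_patch_origins(
            (192, 192, 32), (64, 64, 8), (10, 10, 8), context_dims=(128, 128, 16)
        )
        assert 28 * len(origins) == 4116

    def test_patch_equals_volume_single_patch(self):
        assert plan_volume_patch_origins((64, 64, 8), (64, 64, 8), (1, 1, 1)) == [(0, 0, 0)]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        size=st.integers(8, 200),
        patch=st.integers(1, 64),
        stride=st.integers(1, 32),
        margin=st.integers(0, 16),
    )
    def test_axis_origin_closed_form_vs_enumeration(self, size, patch, stride, margin):
        context = patch + 2 * margin
        got = plan_axis_origins(size, patch, stride, context if margin else None)
        # brute force: every origin where patch and concentric context fit
        valid = [
            o
            for o in range(0, size)
            if o - margin >= 0 and o + patch + margin <= size
        ]
        expected = valid[::stride] if valid else []
        assert got == expected

    def test_context_smaller_than_patch_rejected(self):
        with pytest.raises(ValueError):
            plan_axis_origins(64, 16, 4, context=8)

    def test_restitch_non_overlapping_roundtrip(self, rng):
        x = rng.normal(size=(16, 16, 8)).astype(np.float32)
        ps = extract_volume_patches({"a": x}, (8, 8, 4), (8, 8, 4))
        out = stitch_volume_patches(ps.patches, ps.sources, (16, 16, 8))
        np.testing.assert_array_equal(out, x)

    def test_context_patches_concentric(self, rng):
        x = rng.normal(size=(32, 32, 16)).astype(np.float32)
        ps = extract_volume_patches({"a": x}, (8, 8, 4), (8, 8, 4), context_dims=(16, 16, 8))
        for patch, ctx in zip(ps.patches, ps.context_patches):
            np.testing.assert_array_equal(ctx[4:12, 4:12, 2:6], patch)


class TestSplit:
    def test_thirty_five_subjects_hold_out_seven(self):
        plan = split_cohort([f"s{i}" for i in range(35)], seed=3)
        assert len(plan.test_subjects) == 7
        assert len(plan.train_subjects) == 28

    def test_five_subjects_hold_out_one(self):
        plan = split_cohort([f"s{i}" for i in range(5)], seed=3)
        assert len(plan.test_subjects) == 1

    def test_no_subject_leakage(self):
        plan = split_cohort([f"s{i}" for i in range(10)], seed=0)
        assert not set(plan.train_subjects) & set(plan.test_subjects)

    def test_reproducible(self):
        a = split_cohort([f"s{i}" for i in range(12)], seed=9)
        b = split_cohort([f"s{i}" for i in range(12)], seed=9)
        assert a.test_subjects == b.test_subjects

    def test_patch_assignment_three_to_one(self):
        plan = split_cohort([f"s{i}" for i in range(8)], seed=1)
        tr, val = plan.assign_patches(896)
        assert len(val) == 224  # 896 / 4
        assert len(tr) + len(val) == 896
        assert not set(tr) & set(val)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(["a", "b"], seed=0)


class TestTemporalResample:
    def test_zero_pad_end(self, rng):
        v = vol(rng.normal(size=(4, 4, 2, 20)))
        out = temporal_resample(v, "pad_zero_end", 24)
        assert out.shape[-1] == 24
        np.testing.assert_array_equal(out.data[..., 20:], 0.0)
        np.testing.assert_array_equal(out.data[..., :20], v.data)

    def test_pairwise_averaging(self, rng):
        v = vol(rng.normal(size=(4, 4, 2, 48)))
        out = temporal_resample(v, "average_down", 24)
        assert out.shape[-1] == 24
        expected = v.data.reshape(4, 4, 2, 24, 2).mean(axis=-1)
        np.testing.assert_allclose(out.data, expected, rtol=1e-6)
        assert out.frame_duration == pytest.approx(2 * v.frame_duration)

    def test_linear_up_reproduces_knots(self, rng):
        v = vol(rng.normal(size=(4, 4, 2, 12)))
        out = temporal_resample(v, "linear_up", 24)
        assert out.shape[-1] == 24
        np.testing.assert_allclose(out.data[..., ::2], v.data, atol=1e-6)

    def test_non_integer_downsample_rejected(self):
        with pytest.raises(ValueError):
            temporal_resample(vol(np.zeros((2, 2, 2, 30))), "average_down", 24)


class TestFrameArithmetic:
    @pytest.mark.parametrize(
        "spokes,frames", [(500, 25), (400, 20)]
    )
    def test_spokes_to_frames(self, spokes, frames):
        n, duration = frames_from_spokes(spokes, spokes_per_frame=20, tr_ms=5.0)
        assert n == frames
        assert duration == 100.0

    def test_too_few_spokes_rejected(self):
        with pytest.raises(ValueError):
            frames_from_spokes(10, spokes_per_frame=20)
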