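"""Brightness profile, EDB detection, slice planning and the 4-digit code."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import toothct as tct
from toothct.axis_classification import AxisProfile, CanalConfigurationCode
from toothct.volume_io import BinaryMask, VoxelVolume


def _step_profile(n, k, high=200.0, low=100.0):
    raw = np.full(n, high)
    raw[k:] = low
    return AxisProfile(raw=raw)


class TestBrightnessProfile:
    def test_ramp_volume_gives_identity_profile(self):
        data = np.stack([np.full((4, 4), i, dtype=np.uint8) for i in range(20)])
        profile = tct.brightness_profile(VoxelVolume(data, 10.0))
        assert np.allclose(profile.raw, np.arange(20))

    def test_constant_volume_gives_flat_profile(self):
        profile = tct.brightness_profile(VoxelVolume(np.full((12, 4, 4), 9, np.uint8), 10.0))
        assert np.allclose(profile.raw, 9)

    def test_enamel_brighter_than_dentin_on_phantom(self, mini_volume_truth):
        volume, truth = mini_volume_truth
        raw = tct.brightness_profile(volume).raw
        enamel = raw[truth.first_tooth_slice + 60 : truth.edb_slice]
        dentin = raw[truth.edb_slice : truth.bottom_slice]
        assert enamel.mean() > dentin.mean()


class TestSmoothProfile:
    def test_reproduces_a_linear_ramp(self):
        profile = tct.smooth_profile(AxisProfile(np.linspace(0, 100, 200)), frac=0.1)
        interior = slice(10, 190)
        assert np.allclose(profile.smoothed[interior], profile.raw[interior], atol=0.5)
        assert profile.derivative.size == profile.raw.size

    def test_reduces_variance_on_flat_segments(self, rng):
        raw = np.concatenate([np.full(100, 200.0), np.full(100, 100.0)])
        raw += rng.normal(0, 5, raw.size)
        profile = tct.smooth_profile(AxisProfile(raw), frac=0.1)
        flat = slice(20, 80)
        assert profile.smoothed[flat].var() < profile.raw[flat].var()

    def test_short_profile_is_an_error(self):
        with pytest.raises(ValueError, match="profile too short"):
            tct.smooth_profile(AxisProfile(np.arange(5.0)))


class TestDetectEdb:
    def test_finds_a_constructed_step(self):
        profile = tct.smooth_profile(_step_profile(300, 120), frac=0.05)
        assert abs(tct.detect_edb(profile) - 120) <= 2

    def test_flat_profile_has_no_border(self):
        profile = tct.smooth_profile(AxisProfile(np.full(50, 10.0)))
        with pytest.raises(ValueError, match="no EDB"):
            tct.detect_edb(profile)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(-30, 30))
    def test_translation_equivariance(self, shift):
        base = 120
        edb0 = tct.detect_edb(tct.smooth_profile(_step_profile(300, base), frac=0.05))
        edb1 = tct.detect_edb(tct.smooth_profile(_step_profile(300, base + shift), frac=0.05))
        assert edb1 - edb0 == shift

    def test_matches_phantom_enamel_end(self, mini_volume_truth):
        volume, truth = mini_volume_truth
        cropped, _, box = tct.crop_tooth(volume)
        edb = tct.detect_edb(tct.smooth_profile(tct.brightness_profile(cropped)))
        assert abs(edb + box.start[0] - truth.edb_slice) <= 3


class TestFindBottom:
    def test_last_occupied_slice(self):
        mask = np.zeros((120, 4, 4), dtype=bool)
        mask[:100] = True
        assert tct.find_bottom(BinaryMask(mask, 10.0)) == 99

    def test_single_voxel(self):
        mask = np.zeros((60, 4, 4), dtype=bool)
        mask[42, 1, 2] = True
        assert tct.find_bottom(BinaryMask(mask, 10.0)) == 42

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="no foreground"):
            tct.find_bottom(BinaryMask(np.zeros((5, 4, 4), bool), 10.0))


class TestPlanSlices:
    def test_small_example(self):
        assert tct.plan_slices(0, 9).slice_indices == (0, 3, 6, 9)

    def test_worked_example_landmarks(self):
        # EDB at slice 911, bottom around slice 2341
        plan = tct.plan_slices(911, 2341)
        assert plan.slice_indices == (911, 1388, 1864, 2341)

    def test_degenerate_landmarks_are_an_error(self):
        with pytest.raises(ValueError, match="invalid axis landmarks"):
            tct.plan_slices(10, 10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(5, 3000))
    def test_gaps_differ_by_at_most_one_slice(self, edb, span):
        plan = tct.plan_slices(edb, edb + span)
        gaps = np.diff(plan.slice_indices)
        assert gaps.max() - gaps.min() <= 1


class TestWindowMinProjection:
    def test_single_slice_window_is_that_slice(self):
        data = np.stack([np.full((4, 4), i, np.uint8) for i in range(10)])
        volume = VoxelVolume(data, 10.0)
        out = tct.window_min_projection(volume, 5, window_um=10.0)
        assert (out == 5).all()

    def test_constant_volume_projects_to_constant(self):
        volume = VoxelVolume(np.full((50, 4, 4), 77, np.uint8), 10.0)
        assert (tct.window_min_projection(volume, 25) == 77).all()

    def test_reveals_dark_feature_near_the_center_slice(self):
        data = np.full((60, 8, 8), 120, dtype=np.uint8)
        data[25, 3, 3] = 10  # fine accessory canal 5 slices above center
        volume = VoxelVolume(data, 10.0)
        projected = tct.window_min_projection(volume, 30, window_um=400.0)
        assert projected[3, 3] == 10
        assert volume.data[30, 3, 3] == 120


class TestCountAndClassify:
    def test_empty_and_two_blob_counts(self):
        assert tct.count_canals(np.zeros((8, 8), bool)) == 0
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        assert tct.count_canals(mask) == 2

    def test_count_matches_flood_fill_oracle(self, rng):
        from oracles import flood_fill_components

        for _ in range(10):
            mask = rng.random((24, 24)) < 0.4
            _, sizes = flood_fill_components(mask)
            assert tct.count_canals(mask) == len(sizes)

    def test_code_rendering_and_parsing(self):
        code = CanalConfigurationCode((1, 2, 2), 2)
        assert str(code) == "1-2-2/2"
        assert CanalConfigurationCode.from_string("1-2-2/2") == code

    def test_empty_canal_mask_gives_all_zero_code(self):
        mask = BinaryMask(np.zeros((30, 8, 8), bool), 10.0)
        plan = tct.plan_slices(2, 29)
        assert str(tct.classify_configuration(mask, plan, 0)) == "0-0-0/0"

    def test_phantom_truth_codes(self, mini_volume_truth, mini_bifurcated_volume_truth):
        for (volume, truth), expected in [
            (mini_volume_truth, "1-1-1/1"),
            (mini_bifurcated_volume_truth, "1-2-2/2"),
        ]:
            plan = tct.plan_slices(truth.edb_slice, truth.bottom_slice)
            code = tct.classify_configuration(
                truth.canal_mask, plan, truth.code.main_foramina
            )
            assert str(code) == expected
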