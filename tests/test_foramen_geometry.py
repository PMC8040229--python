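"""Euclidean distance transform, apical window, overlay, foramen rule."""

import numpy as np
import pytest

import toothct as tct
import toothct.foramen_geometry as fg
from toothct.volume_io import BinaryMask, VoxelVolume

from oracles import brute_force_edt


def _tube_mask(shape, radius_vox, center=None):
    """Canal tube running through the whole axial extent (strict rasterization)."""
    nz, nr, nc = shape
    if center is None:
        center = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    disk = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 < radius_vox**2
    return np.broadcast_to(disk, shape).copy()


class TestEuclideanDistanceMap:
    def test_single_voxel_is_one_voxel_deep(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        edt = tct.euclidean_distance_map(BinaryMask(mask, 10.0))
        assert edt.data[2, 2, 2] == pytest.approx(10.0)
        assert edt.data.sum() == pytest.approx(10.0)

    def test_empty_mask_is_all_zero(self):
        edt = tct.euclidean_distance_map(BinaryMask(np.zeros((4, 4, 4), bool), 10.0))
        assert not edt.data.any()

    def test_all_true_mask_is_an_error(self):
        with pytest.raises(ValueError, match="no background"):
            tct.euclidean_distance_map(BinaryMask(np.ones((4, 4, 4), bool), 10.0))

    @pytest.mark.parametrize("radius", [5, 8, 10])
    def test_cylinder_max_edt_within_one_voxel_of_radius(self, radius):
        mask = _tube_mask((30, 41, 41), radius)
        edt = tct.euclidean_distance_map(BinaryMask(mask, 10.0))
        vox = edt.data / 10.0
        for z in range(12, 18):  # mid-slices, clear of the open ends
            assert radius - 1 <= vox[z].max() <= radius

    def test_exact_agreement_with_brute_force(self, rng):
        for _ in range(8):
            mask = rng.random((9, 9, 9)) < 0.5
            if mask.all():
                mask[0, 0, 0] = False
            edt = tct.euclidean_distance_map(BinaryMask(mask, 1.0))
            assert np.allclose(edt.data, brute_force_edt(mask), atol=1e-9)


class TestExtractBottomRegion:
    def test_350_slices_at_10_um(self):
        volume = VoxelVolume(np.zeros((500, 4, 4), np.uint8), 10.0)
        window = tct.extract_bottom_region(volume, 400, height_mm=3.5)
        assert window.n_slices == 350
        assert window.origin_index == 51

    def test_short_volume_is_clipped_not_an_error(self):
        volume = VoxelVolume(np.zeros((100, 4, 4), np.uint8), 10.0)
        window = tct.extract_bottom_region(volume, 99, height_mm=3.5)
        assert window.n_slices == 100
        assert window.origin_index == 0

    def test_window_ends_at_phantom_apex(self, mini_volume_truth):
        volume, truth = mini_volume_truth
        cropped, mask, box = tct.crop_tooth(volume)
        bottom = tct.find_bottom(mask)
        window = tct.extract_bottom_region(cropped, bottom)
        last_global = window.origin_index + window.n_slices - 1
        assert last_global == truth.bottom_slice


class TestOverlayEdt:
    def test_empty_canal_equals_reformatted_reconstruction(self, rng):
        data = rng.integers(0, 199, size=(6, 7, 8), dtype=np.uint8)
        recon = VoxelVolume(data, 10.0)
        edt = fg.DistanceMap(np.zeros((6, 7, 8)), 10.0)
        overlay = tct.overlay_edt(recon, edt)
        assert overlay.shape == (8, 6, 7)
        assert np.array_equal(overlay.data, np.moveaxis(data, 2, 0))

    def test_sagittal_round_trip_is_identity(self, rng):
        data = rng.integers(0, 199, size=(6, 7, 8), dtype=np.uint8)
        recon = VoxelVolume(data, 10.0)
        edt = fg.DistanceMap(np.zeros((6, 7, 8)), 10.0)
        back = tct.sagittal_to_axial(tct.overlay_edt(recon, edt))
        assert np.array_equal(back.data, data)

    def test_cylinder_radius_readable_from_overlay(self):
        mask = _tube_mask((30, 41, 41), 10)
        recon = VoxelVolume(np.full((30, 41, 41), 120, np.uint8), 10.0)
        edt = tct.euclidean_distance_map(BinaryMask(mask, 10.0))
        overlay = tct.overlay_edt(recon, edt)
        encoded = overlay.data[overlay.data >= fg.CANAL_GRAY_BASE] - fg.CANAL_GRAY_BASE
        assert abs(int(encoded.max()) - 10) <= 1

    def test_shape_mismatch_is_an_error(self):
        recon = VoxelVolume(np.zeros((4, 4, 4), np.uint8), 10.0)
        edt = fg.DistanceMap(np.zeros((4, 4, 5)), 10.0)
        with pytest.raises(ValueError, match="misaligned inputs"):
            tct.overlay_edt(recon, edt)


class TestDetectForamina:
    def test_020_mm_rule_is_inclusive(self):
        # radius 10 voxels at 10 um -> diameter exactly 0.20 mm
        mask = BinaryMask(_tube_mask((20, 41, 41), 10), 10.0)
        (found,) = tct.detect_foramina(mask)
        assert found.diameter_um == pytest.approx(200.0)
        assert found.kind == "physiological"

    def test_sub_threshold_opening_is_accessory(self):
        # nominal diameter 0.19 mm measures just below the threshold
        mask = BinaryMask(_tube_mask((20, 41, 41), 9.5), 10.0)
        (found,) = tct.detect_foramina(mask)
        assert found.diameter_um < 200.0
        assert found.kind == "accessory"

    def test_two_tube_phantom_classifies_one_of_each(self):
        shape = (40, 81, 81)
        mask = _tube_mask(shape, 15, center=(40.0, 20.0)) | _tube_mask(
            shape, 5, center=(40.0, 60.0)
        )
        found = tct.detect_foramina(BinaryMask(mask, 10.0))
        kinds = sorted(m.kind for m in found)
        assert kinds == ["accessory", "physiological"]
        assert len(found) == 2  # sum rule: openings = physiological + accessory

    def test_bifurcated_component_yields_two_openings(self, mini_bifurcated_volume_truth):
        _, truth = mini_bifurcated_volume_truth
        found = tct.detect_foramina(truth.canal_mask)
        assert len(found) == 2
        assert all(m.kind == "physiological" for m in found)
        assert sorted(m.diameter_um for m in found) == pytest.approx([200.0, 200.0])

    def test_window_excludes_components_ending_above_it(self):
        mask = np.zeros((30, 21, 21), dtype=bool)
        mask[0:10, 8:13, 8:13] = True   # ends at slice 9, above the window
        mask[0:30, 2:6, 2:6] = True     # reaches the bottom
        found = tct.detect_foramina(BinaryMask(mask, 10.0), apex_window_slices=(20, 30))
        assert len(found) == 1
        assert found[0].exit_slice == 29

    def test_empty_mask_yields_empty_list(self):
        assert tct.detect_foramina(BinaryMask(np.zeros((5, 5, 5), bool), 10.0)) == []
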