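"""Apical foramen geometry via the exact Euclidean distance transform.

Every canal voxel is labeled with its exact Euclidean distance to the canal
wall, so twice the maximal distance across a cross-section is the diameter
of the largest inscribed sphere — the canal diameter at that level.  The
apical 3.5 mm of the tooth is extracted, each apical canal exit is measured
at its lowest cross-section, and openings are classified by the 0.20 mm
rule: diameter >= 0.20 mm is a physiological (main) foramen, anything
smaller is accessory.

For visual reading, the reconstruction and the distance map are merged into
an overlay where canal voxels carry their inscribed-sphere radius (in
voxels) in a reserved high gray band, written as sagittal slices so the
radius can be read off in any image viewer.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, VoxelVolume

__all__ = [
    "DistanceMap",
    "ForamenMeasurement",
    "euclidean_distance_map",
    "extract_bottom_region",
    "overlay_edt",
    "sagittal_to_axial",
    "detect_foramina",
]

#: Apical window height extracted around the root tip (mm).
DEFAULT_BOTTOM_MM = 3.5
#: Foramina with a diameter of at least this value are physiological (µm).
PHYSIOLOGICAL_DIAMETER_UM = 200.0
#: Gray value marking the start of the reserved radius-encoding band in the
#: overlay; canal voxels show CANAL_GRAY_BASE + radius-in-voxels.
CANAL_GRAY_BASE = 200

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass
class DistanceMap:
    """Per-voxel distance to the nearest non-canal voxel, in µm."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")


@dataclasses.dataclass(frozen=True)
class ForamenMeasurement:
    """One apical canal opening.

    ``diameter_um`` is twice the maximal EDT within the exit slice's
    cross-section — the largest inscribed sphere at the opening.
    """

    exit_slice: int
    exit_centroid: tuple[float, float]
    diameter_um: float
    kind: str  # "physiological" | "accessory"


def euclidean_distance_map(
    canal_mask: BinaryMask, voxel_size_um: Optional[float] = None
) -> DistanceMap:
    """Exact 3-D Euclidean distance to the nearest background voxel, in µm."""
    if canal_mask.data.ndim != 3:
        raise ValueError("3-D canal mask required")
    if canal_mask.data.all():
        raise ValueError("no background voxels: distance transform undefined")
    vs = voxel_size_um if voxel_size_um is not None else canal_mask.voxel_size_um
    distances = ndimage.distance_transform_edt(canal_mask.data) * vs
    return DistanceMap(distances, vs)


def extract_bottom_region(
    volume: VoxelVolume, bottom_index: int, height_mm: float = DEFAULT_BOTTOM_MM
) -> VoxelVolume:
    """Axial window of ``height_mm`` ending at ``bottom_index`` (inclusive).

    3.5 mm at 10 µm voxels is 350 slices; the window is clipped at the top
    of the volume when the tooth is shorter.
    """
    if not 0 <= bottom_index < volume.n_slices:
        raise ValueError("bottom_index outside volume")
    n = int(round(height_mm * 1000.0 / volume.voxel_size_um))
    start = max(0, bottom_index + 1 - n)
    data = volume.data[start : bottom_index + 1].copy()
    return VoxelVolume(data, volume.voxel_size_um, origin_index=volume.origin_index + start)


def overlay_edt(recon: VoxelVolume, edt: DistanceMap) -> VoxelVolume:
    """Merge reconstruction and distance map, reformatted to sagittal slices.

    Non-canal voxels keep the reconstruction gray value (compressed below
    the reserved band); canal voxels show ``CANAL_GRAY_BASE + r`` where
    ``r`` is the inscribed-sphere radius rounded to whole voxels, so the
    radius can be read off directly in an image viewer.
    """
    if recon.shape != edt.data.shape:
        raise ValueError("misaligned inputs: reconstruction and EDT shapes differ")
    canal = edt.data > 0
    merged = np.minimum(recon.data, CANAL_GRAY_BASE - 1).astype(np.uint8)
    radius_vox = np.rint(edt.data[canal] / edt.voxel_size_um)
    merged[canal] = CANAL_GRAY_BASE + np.clip(radius_vox, 1, 255 - CANAL_GRAY_BASE).astype(
        np.uint8
    )
    sagittal = np.ascontiguousarray(np.moveaxis(merged, 2, 0))
    return VoxelVolume(sagittal, recon.voxel_size_um, origin_index=0)


def sagittal_to_axial(volume: VoxelVolume) -> VoxelVolume:
    """Inverse reformatting: sagittal slice order back to axial order."""
    return VoxelVolume(
        np.ascontiguousarray(np.moveaxis(volume.data, 0, 2)),
        volume.voxel_size_um,
        origin_index=0,
    )


def detect_foramina(
    canal_mask: BinaryMask,
    edt: Optional[DistanceMap] = None,
    apex_window_slices: Optional[tuple[int, int]] = None,
    min_diameter_um: float = PHYSIOLOGICAL_DIAMETER_UM,
) -> list[ForamenMeasurement]:
    """Measure every apical canal exit and apply the 0.20 mm rule.

    One measurement is produced per apical opening: for every 26-connected
    canal component whose lowest slice lies inside ``apex_window_slices`` (a
    half-open axial index range; default: the whole mask), each 8-connected
    in-plane region of its lowest-slice cross-section is a separate opening
    — a bifurcated canal system is one 3-D component but exits through two
    foramina.  The diameter is twice the maximal in-plane Euclidean
    distance transform of the opening — the largest disk inscribed in it.  The in-plane
    transform is used because per-slice border clearing leaves the canal
    ending at its lowest *closed* cross-section: the 3-D map's value there
    reflects the axial end cap (about one voxel), not the opening.  The kind
    is ``physiological`` iff the diameter reaches ``min_diameter_um``
    (inclusive).  The foramina count depends only on the canal mask, never
    on reconstruction gray values.

    ``edt`` (the 3-D map driving the overlay) is accepted for shape
    validation only.
    """
    if edt is not None and canal_mask.data.shape != edt.data.shape:
        raise ValueError("misaligned inputs: mask and EDT shapes differ")
    labels, n = ndimage.label(canal_mask.data, structure=_STRUCTURE_26)
    if n == 0:
        return []
    lo, hi = apex_window_slices if apex_window_slices is not None else (0, labels.shape[0])
    vs = canal_mask.voxel_size_um
    measurements: list[ForamenMeasurement] = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        zslc = objects[lab - 1][0]
        # lowest slice actually containing this component
        sub = labels[zslc] == lab
        local = np.flatnonzero(sub.any(axis=(1, 2)))
        exit_slice = int(zslc.start + local[-1])
        if not lo <= exit_slice < hi:
            continue
        cross = labels[exit_slice] == lab
        openings, n_open = ndimage.label(cross, structure=np.ones((3, 3), dtype=bool))
        for opening in range(1, n_open + 1):
            region = openings == opening
            diameter = 2.0 * float(ndimage.distance_transform_edt(region).max()) * vs
            rows, cols = np.nonzero(region)
            kind = "physiological" if diameter >= min_diameter_um else "accessory"
            measurements.append(
                ForamenMeasurement(
                    exit_slice=exit_slice,
                    exit_centroid=(float(rows.mean()), float(cols.mean())),
                    diameter_um=diameter,
                    kind=kind,
                )
            )
    measurements.sort(key=lambda m: (-m.exit_slice, m.exit_centroid))
    return measurements
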