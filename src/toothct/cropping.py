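"""Reduce a reconstruction to the smallest cuboid containing the tooth.

A common, fixed gray-value threshold separates tooth from background in
every dataset, 3-D speckles below 1000 voxels are discarded, and the
bounding box of the largest remaining connected component defines the crop.
Cropping only shrinks the data on disk; it never alters voxel values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import morphology

from .volume_io import BinaryMask, VoxelVolume

__all__ = [
    "BoundingBox",
    "foreground_mask",
    "remove_small_components_3d",
    "largest_component_bbox",
    "crop_to_bbox",
    "crop_tooth",
]

#: Default fixed gray-value threshold separating tooth from air (8-bit).
#: The value is data dependent (must sit below dentin and above air/noise);
#: it is exposed everywhere it is used.
DEFAULT_THRESHOLD = 25

#: 3-D speckles smaller than this many voxels are discarded before cropping.
DEFAULT_MIN_VOXELS = 1000

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Half-open per-axis index intervals, 0-based, (axial, row, column)."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self) -> None:
        for a, b in zip(self.start, self.stop):
            if not 0 <= a < b:
                raise ValueError("bounding box intervals must satisfy 0 <= start < stop")

    @property
    def extents(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))  # type: ignore[return-value]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))  # type: ignore[return-value]


def foreground_mask(volume: VoxelVolume, threshold: int = DEFAULT_THRESHOLD) -> BinaryMask:
    """Mask of voxels with gray value strictly above ``threshold``."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in the 8-bit gray range [0, 255]")
    return BinaryMask(volume.data > threshold, volume.voxel_size_um)


def remove_small_components_3d(mask: BinaryMask, min_voxels: int = DEFAULT_MIN_VOXELS) -> BinaryMask:
    """Drop 26-connected components with fewer than ``min_voxels`` voxels.

    The rule is strict: a 999-voxel speckle goes, a 1000-voxel component
    stays (at the default).
    """
    if mask.data.ndim != 3:
        raise ValueError("3-D mask required")
    # max_size removes components of size <= max_size, so the strict rule
    # 'smaller than min_voxels is a speckle' needs max_size = min_voxels - 1
    cleaned = morphology.remove_small_objects(
        mask.data, connectivity=3, max_size=min_voxels - 1
    )
    return BinaryMask(cleaned, mask.voxel_size_um)


def largest_component_bbox(mask: BinaryMask) -> BoundingBox:
    """Tight bounding box of the 26-connected component with the most voxels.

    Ties between equal-size components are broken toward the smallest axial
    start index, for determinism.
    """
    labels, n = ndimage.label(mask.data, structure=_STRUCTURE_26)
    if n == 0:
        raise ValueError("no foreground voxels in mask")
    counts = np.bincount(labels.ravel())[1:]
    objects = ndimage.find_objects(labels)
    biggest = counts.max()
    candidates = np.flatnonzero(counts == biggest)
    best = min(candidates, key=lambda i: objects[i][0].start)
    slc = objects[best]
    return BoundingBox(
        start=tuple(s.start for s in slc),  # type: ignore[arg-type]
        stop=tuple(s.stop for s in slc),  # type: ignore[arg-type]
    )


def crop_to_bbox(volume: VoxelVolume, box: BoundingBox) -> VoxelVolume:
    """Crop a volume to ``box``; ``origin_index`` advances by the axial start."""
    for a, b, n in zip(box.start, box.stop, volume.shape):
        if not (0 <= a < b <= n):
            raise ValueError("bbox outside volume")
    data = volume.data[box.slices].copy()
    return VoxelVolume(
        data, volume.voxel_size_um, origin_index=volume.origin_index + box.start[0]
    )


def crop_tooth(
    volume: VoxelVolume,
    threshold: int = DEFAULT_THRESHOLD,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> tuple[VoxelVolume, BinaryMask, BoundingBox]:
    """Full cropping stage: threshold, despeckle, crop to the largest object.

    Returns the cropped volume, the denoised tooth mask cropped to the same
    box, and the box itself (in the input volume's coordinates).
    """
    mask = remove_small_components_3d(foreground_mask(volume, threshold), min_voxels)
    box = largest_component_bbox(mask)
    cropped = crop_to_bbox(volume, box)
    cropped_mask = BinaryMask(mask.data[box.slices].copy(), mask.voxel_size_um)
    return cropped, cropped_mask, box
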