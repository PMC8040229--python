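"""Quick-look images: middle slices, maximum-intensity projections, montages.

The coronal and sagittal directions of a rotationally unoriented tooth scan
are simply the two dataset axes orthogonal to the axial axis; they carry no
anatomical meaning.
"""

from __future__ import annotations

import math
from typing import Sequence, Union

import numpy as np

from .volume_io import VoxelVolume

__all__ = ["middle_slices", "max_intensity_projection", "montage", "AXIS_NAMES"]

AXIS_NAMES = {"axial": 0, "coronal": 1, "sagittal": 2}


def middle_slices(volume: VoxelVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The slice at index ``floor(n/2)`` along each of the three axes."""
    return tuple(
        np.take(volume.data, volume.data.shape[axis] // 2, axis=axis)
        for axis in range(3)
    )  # type: ignore[return-value]


def max_intensity_projection(volume: VoxelVolume, axis: Union[str, int] = "axial") -> np.ndarray:
    """Element-wise maximum gray value along one anatomical axis."""
    if isinstance(axis, str):
        try:
            axis = AXIS_NAMES[axis]
        except KeyError:
            raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(AXIS_NAMES)}")
    return volume.data.max(axis=axis)


def montage(previews: Sequence[np.ndarray], columns: int = 6) -> np.ndarray:
    """Row-major grid of 2-D images, zero-padded to a uniform tile size."""
    if len(previews) == 0:
        raise ValueError("montage needs at least one image")
    if columns < 1:
        raise ValueError("columns must be >= 1")
    tile_h = max(img.shape[0] for img in previews)
    tile_w = max(img.shape[1] for img in previews)
    rows = math.ceil(len(previews) / columns)
    dtype = np.result_type(*[img.dtype for img in previews])
    out = np.zeros((rows * tile_h, columns * tile_w), dtype=dtype)
    for i, img in enumerate(previews):
        r, c = divmod(i, columns)
        out[r * tile_h : r * tile_h + img.shape[0], c * tile_w : c * tile_w + img.shape[1]] = img
    return out
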