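"""Slice-stack input/output, scanner-log parsing and chunked volume stores.

Micro-CT scanners deliver a reconstructed tooth as a directory of axial
gray-scale slice images (PNG or TIFF, 8-bit, isometric voxels) plus a
key/value log file with the acquisition parameters.  This module turns such
a directory into an in-memory :class:`VoxelVolume`, extracts the acquisition
metadata, and persists volumes as chunked, compressed zarr stores — the
on-disk layout every downstream stage consumes.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import zarr

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "ScanMetadata",
    "read_reconstruction_stack",
    "parse_scan_log",
    "write_chunked_store",
    "read_chunked_store",
]

#: File extensions accepted as reconstruction slices.
SLICE_EXTENSIONS = (".png", ".tif", ".tiff")


@dataclasses.dataclass
class VoxelVolume:
    """A 3-D gray-value image stack with an isometric physical voxel size.

    Axis 0 is the axial slice index and increases from the crown toward the
    apex of the tooth.  ``origin_index`` records the axial index of slice 0
    in the uncropped parent stack, so measurements on a cropped volume can
    always be reported in the coordinates of the original reconstruction.
    """

    data: np.ndarray
    voxel_size_um: float
    origin_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a non-empty 3-D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclasses.dataclass
class BinaryMask:
    """Boolean mask aligned voxel-for-voxel with a source volume (or slice)."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim not in (2, 3):
            raise ValueError("mask must be 2-D or 3-D")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclasses.dataclass
class ScanMetadata:
    """Acquisition parameters parsed from a scanner log file."""

    voxel_size_um: float
    tube_voltage_kv: Optional[float] = None
    tube_current_ua: Optional[float] = None
    filter_description: Optional[str] = None
    exposure_ms: Optional[float] = None
    rotation_step_deg: Optional[float] = None
    frame_averaging: Optional[int] = None
    ring_artifact_setting: Optional[float] = None
    stack_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if self.tube_voltage_kv is not None and not self.tube_voltage_kv > 0:
            raise ValueError("tube_voltage_kv must be positive")


def _load_slice(path: Path) -> np.ndarray:
    try:
        img = iio.imread(path)
    except Exception as exc:  # unreadable / truncated file
        raise ValueError(f"decode failure: {path.name}") from exc
    if img.ndim == 3:
        # Gray image saved with redundant color channels.
        if img.shape[-1] in (3, 4) and np.array_equal(img[..., 0], img[..., 1]):
            img = img[..., 0]
        else:
            raise ValueError(f"decode failure: {path.name} (not a gray-scale image)")
    if img.dtype == np.uint16:
        warnings.warn(
            f"{path.name}: 16-bit slice rescaled linearly to 8-bit", stacklevel=3
        )
        img = np.round(img.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    elif img.dtype != np.uint8:
        raise ValueError(f"decode failure: {path.name} (unsupported bit depth {img.dtype})")
    return img


def read_reconstruction_stack(directory, voxel_size_um: float) -> VoxelVolume:
    """Read a directory of axial reconstruction slices into a volume.

    Slices are stacked in strict lexicographic file-name order (scanner
    output is zero-padded, so this is also the acquisition order) and the
    result is independent of file creation order.  All slices must share one
    width, height and bit depth; 16-bit input is rescaled to 8-bit with a
    warning.
    """
    directory = Path(directory)
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in SLICE_EXTENSIONS),
        key=lambda p: p.name,
    )
    if not files:
        raise ValueError(f"no slices found in {directory}")
    slices = []
    for path in files:
        img = _load_slice(path)
        if slices and img.shape != slices[0].shape:
            raise ValueError(
                f"ragged stack: {path.name} has shape {img.shape}, "
                f"expected {slices[0].shape}"
            )
        slices.append(img)
    return VoxelVolume(np.stack(slices, axis=0), voxel_size_um, origin_index=0)


# Scanner-log key synonyms, matched case-insensitively after stripping
# whitespace.  The log schema is scanner specific; this list covers the
# Bruker/SkyScan dialect and is a maintained guess — extend as needed.
_LOG_SYNONYMS: dict[str, tuple[str, ...]] = {
    "voxel_size_um": ("image pixel size (um)", "pixel size (um)", "voxel size (um)"),
    "tube_voltage_kv": ("source voltage (kv)", "voltage (kv)"),
    "tube_current_ua": ("source current (ua)", "current (ua)"),
    "filter_description": ("filter",),
    "exposure_ms": ("exposure (ms)", "exposure time (ms)", "exposure (msec)"),
    "rotation_step_deg": ("rotation step (deg)", "rotation step (degree)"),
    "frame_averaging": ("frame averaging", "averaging frames"),
    "ring_artifact_setting": ("ring artifact correction", "ringartifact correction"),
    "stack_count": ("number of connected scans", "connected scans"),
}

_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?")


def _first_number(text: str) -> Optional[float]:
    m = _NUMBER_RE.search(text)
    return float(m.group()) if m else None


def parse_scan_log(log_text: str) -> ScanMetadata:
    """Parse an INI-style ``Key=Value`` scanner log into :class:`ScanMetadata`.

    Section headers and unknown keys are ignored; numeric fields tolerate
    decorations such as ``ON (3)``.  A log without a pixel-size entry cannot
    anchor any physical measurement and raises ``incomplete log``.
    """
    raw: dict[str, str] = {}
    for line in log_text.splitlines():
        line = line.strip()
        if not line or line.startswith("[") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        raw[key.strip().lower()] = value.strip()

    found: dict[str, str] = {}
    for field, synonyms in _LOG_SYNONYMS.items():
        for syn in synonyms:
            if syn in raw:
                found[field] = raw[syn]
                break

    if "voxel_size_um" not in found:
        raise ValueError("incomplete log: no pixel-size entry found")
    voxel_size = _first_number(found["voxel_size_um"])
    if voxel_size is None or voxel_size <= 0:
        raise ValueError("incomplete log: pixel-size entry is not a positive number")

    def num(field: str) -> Optional[float]:
        return _first_number(found[field]) if field in found else None

    def integer(field: str) -> Optional[int]:
        value = num(field)
        return int(value) if value is not None else None

    return ScanMetadata(
        voxel_size_um=voxel_size,
        tube_voltage_kv=num("tube_voltage_kv"),
        tube_current_ua=num("tube_current_ua"),
        filter_description=found.get("filter_description"),
        exposure_ms=num("exposure_ms"),
        rotation_step_deg=num("rotation_step_deg"),
        frame_averaging=integer("frame_averaging"),
        ring_artifact_setting=num("ring_artifact_setting"),
        stack_count=integer("stack_count"),
    )


def write_chunked_store(volume: VoxelVolume, store_path, chunk_slices: int = 1):
    """Write a volume to a chunked, compressed zarr store.

    The default chunk shape is one axial slice per chunk, matching the
    per-slice access pattern of the canal-extraction stage.  Voxel size and
    origin index travel as array attributes so the round trip is lossless.
    """
    nz, ny, nx = volume.shape
    arr = zarr.create_array(
        store=str(store_path),
        shape=volume.shape,
        chunks=(max(1, int(chunk_slices)), ny, nx),
        dtype=volume.data.dtype,
        overwrite=True,
    )
    arr[:] = volume.data
    arr.attrs.update(
        {"voxel_size_um": float(volume.voxel_size_um), "origin_index": int(volume.origin_index)}
    )
    return arr


def read_chunked_store(store_path) -> VoxelVolume:
    """Read a volume previously written by :func:`write_chunked_store`."""
    try:
        arr = zarr.open_array(str(store_path), mode="r")
        data = arr[:]
        voxel_size = float(arr.attrs["voxel_size_um"])
        origin = int(arr.attrs.get("origin_index", 0))
    except Exception as exc:
        raise ValueError(f"store unreadable: {store_path}") from exc
    return VoxelVolume(data, voxel_size, origin_index=origin)
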