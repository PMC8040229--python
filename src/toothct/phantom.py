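"""Synthetic micro-CT tooth phantoms with exact analytic ground truth.

A phantom emulates the gray-value structure of a reconstructed single-rooted
tooth: a bright enamel cap over a darker dentin body, near-background canal
lumina of specified radii with branch/merge topology, surrounding air, and
optional additive Gaussian noise.  The tooth body is a surface of
revolution: a dome-shaped crown (cross-section area growing linearly toward
the enamel–dentin border), a cylindrical root and a tapered apex.

Ground truth — canal mask, EDB slice, configuration code and foramen
diameters — is computed from the tube geometry, never by segmenting the
rendered image, so validation against it is not circular.

Geometry scale: real scans are ~2700 slices at 10 µm (~27 mm of tooth).
The default suite keeps the 10 µm voxel size, the gray-level ordering and
every pixel/voxel threshold of the processing chain, but uses 420-slice
volumes so a whole 12-phantom suite renders and processes in minutes on one
CPU.  Canal lumina run through to the tooth's bottom slice — the open
apical foramen — so the exit cross-section of each canal is measured
in-plane.

Disks are rasterized with a strict inequality (center distance < radius)
and the default in-plane dimensions are odd so tube centers sit on the
voxel lattice: for an integer radius ``r`` the maximal EDT of a
cross-section is then exactly ``r`` voxels, making nominal and measured
foramen diameters agree.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

from .axis_classification import CanalConfigurationCode, count_canals, plan_slices
from .volume_io import BinaryMask, VoxelVolume

__all__ = [
    "CanalSegment",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "default_phantom_suite",
    "suite_codes",
    "write_phantom_stack",
]

#: Configuration codes covered by the default suite.
SUITE_CODES = ("1-1-1/1", "1-2-1/1", "1-2-2/2", "2-2-2/2", "2-1-1/1", "1-1-2/2")


@dataclasses.dataclass(frozen=True)
class CanalSegment:
    """A straight canal tube between two axial slices (inclusive).

    The in-plane center moves linearly from ``start_center`` to
    ``end_center`` (row, column, in voxels).  Segments chain when the next
    one starts on the slice following this one's end; a segment with no
    successor is an apical exit.
    """

    start_slice: int
    end_slice: int
    start_center: tuple[float, float]
    end_center: tuple[float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if self.end_slice < self.start_slice:
            raise ValueError("segment must not end before it starts")
        if not self.radius_um > 0:
            raise ValueError("segment radius must be positive")

    def center_at(self, z: int) -> tuple[float, float]:
        span = self.end_slice - self.start_slice
        t = 0.0 if span == 0 else (z - self.start_slice) / span
        return (
            self.start_center[0] + t * (self.end_center[0] - self.start_center[0]),
            self.start_center[1] + t * (self.end_center[1] - self.start_center[1]),
        )


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full geometric and photometric description of one phantom.

    Gray levels follow the ordering micro-CT attenuation imposes
    (enamel > dentin > canal ≈ air) with headroom for additive noise.
    """

    canal_tree: tuple[CanalSegment, ...]
    shape: tuple[int, int, int] = (420, 141, 141)
    voxel_size_um: float = 10.0
    crown_tip_slice: int = 4
    crown_full_slice: int = 100
    enamel_end_slice: int = 130
    taper_start_slice: int = 365
    bottom_slice: int = 415
    body_radius_um: float = 550.0
    apex_radius_um: float = 400.0
    gray_air: int = 5
    gray_canal: int = 10
    gray_dentin: int = 120
    gray_enamel: int = 220
    noise_sigma: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not (
            self.gray_enamel > self.gray_dentin > self.gray_canal >= self.gray_air
        ):
            raise ValueError("gray levels must satisfy enamel > dentin > canal >= air")
        if not (
            self.crown_tip_slice
            < self.crown_full_slice
            <= self.enamel_end_slice
            < self.taper_start_slice
            < self.bottom_slice
            < self.shape[0]
        ):
            raise ValueError("axial landmarks out of order")
        if not self.canal_tree:
            raise ValueError("phantom needs at least one canal segment")

    def body_radius_vox(self, z: int) -> float:
        """Tooth cross-section radius at slice ``z``, in voxels (0 = air)."""
        r_full = self.body_radius_um / self.voxel_size_um
        r_apex = self.apex_radius_um / self.voxel_size_um
        if z < self.crown_tip_slice or z > self.bottom_slice:
            return 0.0
        if z < self.crown_full_slice:
            # dome: cross-section area grows linearly from tip to full radius
            frac = (z - self.crown_tip_slice + 1) / (
                self.crown_full_slice - self.crown_tip_slice + 1
            )
            return r_full * math.sqrt(frac)
        if z <= self.taper_start_slice:
            return r_full
        frac = (z - self.taper_start_slice) / (self.bottom_slice - self.taper_start_slice)
        return r_full + frac * (r_apex - r_full)


@dataclasses.dataclass
class PhantomTruth:
    """Exact ground truth, derived from the geometry of a PhantomSpec."""

    canal_mask: BinaryMask
    edb_slice: int
    bottom_slice: int
    first_tooth_slice: int
    code: CanalConfigurationCode
    foramen_diameters_um: tuple[float, ...]


def _disk(center: tuple[float, float], radius_vox: float,
          rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    dr = rows - center[0]
    dc = cols - center[1]
    return dr * dr + dc * dc < radius_vox * radius_vox


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Voxelize a phantom and return it with its analytic ground truth.

    Deterministic for a fixed seed (NumPy PCG64); noise is Gaussian,
    truncated to the 8-bit range.
    """
    nz, nr, nc = spec.shape
    rows, cols = np.meshgrid(np.arange(nr, dtype=float), np.arange(nc, dtype=float),
                             indexing="ij")
    axis_center = ((nr - 1) / 2.0, (nc - 1) / 2.0)

    body = np.zeros(spec.shape, dtype=bool)
    for z in range(nz):
        r = spec.body_radius_vox(z)
        if r > 0:
            body[z] = _disk(axis_center, r, rows, cols)

    canal = np.zeros(spec.shape, dtype=bool)
    for seg in spec.canal_tree:
        radius_vox = seg.radius_um / spec.voxel_size_um
        for z in range(max(0, seg.start_slice), min(nz - 1, seg.end_slice) + 1):
            canal[z] |= _disk(seg.center_at(z), radius_vox, rows, cols)

    if np.any(canal & ~body):
        raise ValueError("invalid spec: canal segment outside the tooth body")

    volume = np.full(spec.shape, spec.gray_air, dtype=np.uint8)
    volume[body] = spec.gray_dentin
    enamel_zone = body.copy()
    enamel_zone[spec.enamel_end_slice:] = False
    volume[enamel_zone] = spec.gray_enamel
    volume[canal] = spec.gray_canal

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = volume.astype(np.float64) + rng.normal(0.0, spec.noise_sigma, spec.shape)
        volume = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    truth = _derive_truth(spec, canal)
    return VoxelVolume(volume, spec.voxel_size_um), truth


def _derive_truth(spec: PhantomSpec, canal: np.ndarray) -> PhantomTruth:
    plan = plan_slices(spec.enamel_end_slice, spec.bottom_slice)
    counts = tuple(count_canals(canal[i]) for i in plan.slice_indices[:3])
    successors = {seg.start_slice for seg in spec.canal_tree}
    exits = [seg for seg in spec.canal_tree if seg.end_slice + 1 not in successors]
    exits.sort(key=lambda s: s.end_center)
    diameters = tuple(2.0 * seg.radius_um for seg in exits)
    main = sum(1 for d in diameters if d >= 200.0)
    return PhantomTruth(
        canal_mask=BinaryMask(canal, spec.voxel_size_um),
        edb_slice=spec.enamel_end_slice,
        bottom_slice=spec.bottom_slice,
        first_tooth_slice=spec.crown_tip_slice,
        code=CanalConfigurationCode(counts, main),  # type: ignore[arg-type]
        foramen_diameters_um=diameters,
    )


# --------------------------------------------------------------------------
# Default suite: one canal-tree builder per configuration code.
#
# Axial layout (default spec): EDB at 130, bottom at 415, so the planned
# classification slices are [130, 225, 320, 415].  Branch and merge
# transitions are placed at 175–191 and 255–271 — at least 30 slices away
# from any counting slice, so the recovered code is stable against the ±3
# slice EDB tolerance.  Exits converge toward the axis to stay inside the
# tapered apex and always end on the bottom slice (open apical foramen).
# --------------------------------------------------------------------------

_CANAL_TOP = 50          # canal starts inside the crown, above the EDB
_BRANCH_A = (175, 191)   # diverge window between EDB and first counting slice
_BRANCH_B = (255, 271)   # diverge/merge window between the middle counting slices
_CONVERGE = 370          # exits start converging toward the axis here
_OFFSET = 22.0           # in-plane branch offset, voxels
_EXIT_OFFSET = 14.0      # exit offset at the bottom slice, voxels


def _c(row_off: float = 0.0, col_off: float = 0.0,
       shape: tuple[int, int, int] = (420, 141, 141)) -> tuple[float, float]:
    return ((shape[1] - 1) / 2.0 + row_off, (shape[2] - 1) / 2.0 + col_off)


def _tree_for_code(code: str, bottom: int = 415) -> tuple[CanalSegment, ...]:
    """Canal tree realizing one of the suite configuration codes."""
    mid = _c()
    left, right = _c(0, -_OFFSET), _c(0, +_OFFSET)
    exit_left, exit_right = _c(0, -_EXIT_OFFSET), _c(0, +_EXIT_OFFSET)
    a0, a1 = _BRANCH_A
    b0, b1 = _BRANCH_B

    def straight(z0, z1, center, r):
        return CanalSegment(z0, z1, center, center, r)

    def moving(z0, z1, c_from, c_to, r):
        return CanalSegment(z0, z1, c_from, c_to, r)

    if code == "1-1-1/1":
        return (straight(_CANAL_TOP, bottom, mid, 120.0),)
    if code == "1-2-1/1":
        return (
            straight(_CANAL_TOP, a0 - 1, mid, 100.0),
            moving(a0, a1, mid, left, 90.0),
            moving(a0, a1, mid, right, 90.0),
            straight(a1 + 1, b0 - 1, left, 90.0),
            straight(a1 + 1, b0 - 1, right, 90.0),
            moving(b0, b1, left, _c(0, -5.0), 90.0),
            moving(b0, b1, right, _c(0, +5.0), 90.0),
            straight(b1 + 1, bottom, mid, 120.0),
        )
    if code == "1-2-2/2":
        return (
            straight(_CANAL_TOP, a0 - 1, mid, 100.0),
            moving(a0, a1, mid, left, 100.0),
            moving(a0, a1, mid, right, 100.0),
            straight(a1 + 1, _CONVERGE - 1, left, 120.0),
            straight(a1 + 1, _CONVERGE - 1, right, 100.0),
            moving(_CONVERGE, bottom, left, exit_left, 120.0),
            moving(_CONVERGE, bottom, right, exit_right, 100.0),
        )
    if code == "2-2-2/2":
        return (
            straight(_CANAL_TOP, _CONVERGE - 1, left, 120.0),
            straight(_CANAL_TOP, _CONVERGE - 1, right, 100.0),
            moving(_CONVERGE, bottom, left, exit_left, 120.0),
            moving(_CONVERGE, bottom, right, exit_right, 100.0),
        )
    if code == "2-1-1/1":
        return (
            straight(_CANAL_TOP, 152, left, 90.0),
            straight(_CANAL_TOP, 152, right, 90.0),
            moving(153, 168, left, _c(0, -5.0), 90.0),
            moving(153, 168, right, _c(0, +5.0), 90.0),
            straight(169, bottom, mid, 120.0),
        )
    if code == "1-1-2/2":
        return (
            straight(_CANAL_TOP, b0 - 1, mid, 100.0),
            moving(b0, b1, mid, left, 100.0),
            moving(b0, b1, mid, right, 100.0),
            straight(b1 + 1, _CONVERGE - 1, left, 120.0),
            straight(b1 + 1, _CONVERGE - 1, right, 100.0),
            moving(_CONVERGE, bottom, left, exit_left, 120.0),
            moving(_CONVERGE, bottom, right, exit_right, 100.0),
        )
    raise ValueError(f"no canal tree defined for code {code!r}")


def default_phantom_suite() -> list[PhantomSpec]:
    """Twelve phantoms: six configuration codes, each at noise σ ∈ {0, 10}."""
    specs = []
    for i, code in enumerate(SUITE_CODES):
        for sigma in (0.0, 10.0):
            specs.append(
                PhantomSpec(
                    canal_tree=_tree_for_code(code),
                    noise_sigma=sigma,
                    seed=1000 + 100 * i + int(sigma),
                    name=f"{code} sigma={sigma:g}",
                )
            )
    return specs


def suite_codes() -> tuple[str, ...]:
    return SUITE_CODES


def write_phantom_stack(
    spec: PhantomSpec, out_dir, write_log: bool = True
) -> tuple[VoxelVolume, PhantomTruth]:
    """Render a phantom to a PNG slice stack + truth JSON, pipeline-ready.

    The directory is directly consumable by ``read_reconstruction_stack``
    and the batch pipeline; a minimal scanner-style log carries the voxel
    size.  The truth JSON is labeled synthetic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume, truth = generate_phantom(spec)
    for z in range(volume.n_slices):
        iio.imwrite(out_dir / f"slice_{z:04d}.png", volume.data[z])
    if write_log:
        (out_dir / "phantom.log").write_text(
            "[System]\n"
            "Scanner=synthetic phantom generator\n"
            "[Acquisition]\n"
            "Source Voltage (kV)=80\n"
            "Source Current (uA)=125\n"
            f"Image Pixel Size (um)={spec.voxel_size_um:g}\n"
            "Filter=Al 1mm\n"
            "Rotation Step (deg)=0.4\n"
            "Frame Averaging=ON (3)\n"
        )
    truth_payload = {
        "synthetic": True,
        "name": spec.name,
        "code": str(truth.code),
        "edb_slice": truth.edb_slice,
        "bottom_slice": truth.bottom_slice,
        "first_tooth_slice": truth.first_tooth_slice,
        "foramen_diameters_um": list(truth.foramen_diameters_um),
        "voxel_size_um": spec.voxel_size_um,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_payload, indent=2))
    return volume, truth
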