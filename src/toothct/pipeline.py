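"""Batch orchestration: process tooth directories end-to-end, incrementally.

Mirrors the incremental notebook workflow the method was designed around:
discover tooth directories under a root, process each one through
read → crop → overview → canal extraction → classification → foramen
geometry, persist every artifact, and skip directories whose report was
already produced with the same configuration.  Re-running a batch after new
teeth were scanned computes only the new rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

import imageio.v3 as iio  # noqa: E402

from . import axis_classification as axcls  # noqa: E402
from . import canal_extraction as canal  # noqa: E402
from . import cropping  # noqa: E402
from . import foramen_geometry as foramen  # noqa: E402
from . import overview  # noqa: E402
from . import volume_io  # noqa: E402

__all__ = ["PipelineConfig", "ToothReport", "process_tooth", "batch", "load_config"]

logger = logging.getLogger("toothct")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the pipeline, in one place.

    ``voxel_size_um`` is the fallback used when a tooth directory carries no
    scanner log.  ``edb_slice`` (original-stack index) overrides the
    automatic enamel–dentin-border detection for teeth whose metal fillings
    dominate the brightness profile.
    """

    crop_threshold: int = cropping.DEFAULT_THRESHOLD
    min_speckle_voxels: int = cropping.DEFAULT_MIN_VOXELS
    min_canal_area_px: int = canal.DEFAULT_MIN_AREA_PX
    max_canal_hole_px: int = canal.DEFAULT_MAX_HOLE_PX
    lowess_frac: float = axcls.DEFAULT_LOWESS_FRAC
    window_um: float = axcls.DEFAULT_WINDOW_UM
    bottom_mm: float = foramen.DEFAULT_BOTTOM_MM
    min_foramen_diameter_mm: float = 0.2
    voxel_size_um: float = 10.0
    edb_slice: Optional[int] = None
    montage_columns: int = 6
    chunk_slices: int = 1
    write_overlay: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a TOML file (unknown keys rejected)."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclasses.dataclass
class ToothReport:
    """Everything the pipeline derived for one tooth."""

    tooth_id: str
    status: str = "pending"  # pending | complete | cached | failed
    failed_stage: Optional[str] = None
    error: Optional[str] = None
    metadata: Optional[dict] = None
    bounding_box: Optional[dict] = None
    edb_index: Optional[int] = None
    edb_source: Optional[str] = None
    bottom_index: Optional[int] = None
    slice_indices: Optional[list] = None
    canal_counts: Optional[list] = None
    code: Optional[str] = None
    foramina: Optional[list] = None
    length_mm: Optional[float] = None
    artifacts: Optional[dict] = None
    config_hash: Optional[str] = None
    timings_s: Optional[dict] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "ToothReport":
        valid = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in payload.items() if k in valid})


def _write_png(path: Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def _report_figure(path, profile, plan, windows, counts, code) -> None:
    """Per-tooth report: brightness profile with landmarks + the four
    min-projection windows (the manual-characterization aid)."""
    fig, axes = plt.subplots(1, 5, figsize=(16, 4))
    ax = axes[0]
    ax.plot(profile.raw, lw=0.7, label="raw")
    ax.plot(profile.smoothed, lw=1.2, label="smoothed")
    for idx in plan.slice_indices:
        ax.axvline(idx, color="0.6", ls="--", lw=0.7)
    ax.axvline(plan.edb_index, color="tab:red", ls="-", lw=1.0, label="EDB")
    ax.set_xlabel("axial slice")
    ax.set_ylabel("mean gray value")
    ax.legend(fontsize=7)
    ax.set_title(f"code {code}")
    labels = ["EDB", "upper", "lower", "bottom"]
    for i, (win, lab) in enumerate(zip(windows, labels)):
        axes[i + 1].imshow(win, cmap="gray", vmin=0, vmax=255)
        count_note = f" ({counts[i]} canal(s))" if i < len(counts) else ""
        axes[i + 1].set_title(f"{lab} @ {plan.slice_indices[i]}{count_note}", fontsize=8)
        axes[i + 1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def process_tooth(directory, config: Optional[PipelineConfig] = None, out_dir=None) -> ToothReport:
    """Run the whole pipeline on one tooth directory.

    Deterministic given the configuration.  Any stage error marks the
    report failed with the stage name instead of raising, so a batch
    continues past broken datasets.  A report already produced with the
    same configuration short-circuits to ``status="cached"``.
    """
    directory = Path(directory)
    config = config or PipelineConfig()
    out_dir = Path(out_dir) if out_dir is not None else directory / "analysis"
    report_path = out_dir / "report.json"

    if report_path.exists():
        try:
            cached = ToothReport.from_dict(json.loads(report_path.read_text()))
        except (json.JSONDecodeError, TypeError):
            cached = None
        if cached and cached.status == "complete" and cached.config_hash == config.config_hash:
            cached.status = "cached"
            return cached

    report = ToothReport(tooth_id=directory.name, config_hash=config.config_hash)
    artifacts: dict = {}
    timings: dict = {}
    stage = "read"
    try:
        t0 = time.perf_counter()
        voxel_size = config.voxel_size_um
        logs = sorted(directory.glob("*.log"))
        if logs:
            meta = volume_io.parse_scan_log(logs[0].read_text())
            report.metadata = dataclasses.asdict(meta)
            voxel_size = meta.voxel_size_um
        volume = volume_io.read_reconstruction_stack(directory, voxel_size)
        out_dir.mkdir(parents=True, exist_ok=True)
        timings[stage] = time.perf_counter() - t0

        stage = "crop"
        t0 = time.perf_counter()
        cropped, tooth_mask, box = cropping.crop_tooth(
            volume, config.crop_threshold, config.min_speckle_voxels
        )
        report.bounding_box = {"start": list(box.start), "stop": list(box.stop)}
        volume_io.write_chunked_store(cropped, out_dir / "cropped.zarr", config.chunk_slices)
        artifacts["cropped_store"] = str(out_dir / "cropped.zarr")
        timings[stage] = time.perf_counter() - t0

        stage = "overview"
        t0 = time.perf_counter()
        mid_ax, mid_cor, mid_sag = overview.middle_slices(cropped)
        for name, img in [
            ("middle_axial", mid_ax),
            ("middle_coronal", mid_cor),
            ("middle_sagittal", mid_sag),
            ("mip_axial", overview.max_intensity_projection(cropped, "axial")),
            ("mip_coronal", overview.max_intensity_projection(cropped, "coronal")),
            ("mip_sagittal", overview.max_intensity_projection(cropped, "sagittal")),
        ]:
            _write_png(out_dir / f"{name}.png", img)
            artifacts[name] = str(out_dir / f"{name}.png")
        timings[stage] = time.perf_counter() - t0

        stage = "canal"
        t0 = time.perf_counter()
        canal_mask = canal.extract_canal_volume(
            cropped, config.min_canal_area_px, config.max_canal_hole_px
        )
        canal_store = volume_io.VoxelVolume(
            canal_mask.data.astype(np.uint8), cropped.voxel_size_um, cropped.origin_index
        )
        volume_io.write_chunked_store(canal_store, out_dir / "canal.zarr", config.chunk_slices)
        artifacts["canal_store"] = str(out_dir / "canal.zarr")
        timings[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        profile = axcls.smooth_profile(axcls.brightness_profile(cropped), config.lowess_frac)
        if config.edb_slice is not None:
            edb = int(config.edb_slice) - cropped.origin_index
            source = "manual"
            if not 0 <= edb < cropped.n_slices:
                raise ValueError("manual EDB slice lies outside the cropped volume")
        else:
            edb = axcls.detect_edb(profile)
            source = "automatic"
        bottom = axcls.find_bottom(tooth_mask)
        plan = axcls.plan_slices(edb, bottom, config.window_um, source)
        windows = [
            axcls.window_min_projection(cropped, idx, config.window_um)
            for idx in plan.slice_indices
        ]
        counts = [int(axcls.count_canals(canal_mask.data[i])) for i in plan.slice_indices[:3]]
        report.edb_index = edb + cropped.origin_index
        report.edb_source = source
        report.bottom_index = bottom + cropped.origin_index
        report.slice_indices = [i + cropped.origin_index for i in plan.slice_indices]
        report.canal_counts = counts
        report.length_mm = float((bottom + 1) * cropped.voxel_size_um / 1000.0)
        timings[stage] = time.perf_counter() - t0

        stage = "foramen"
        t0 = time.perf_counter()
        apical_recon = foramen.extract_bottom_region(cropped, bottom, config.bottom_mm)
        window_start = apical_recon.origin_index - cropped.origin_index
        apical_mask = volume_io.BinaryMask(
            canal_mask.data[window_start : bottom + 1], canal_mask.voxel_size_um
        )
        if apical_mask.data.any():
            edt = foramen.euclidean_distance_map(apical_mask)
            measurements = foramen.detect_foramina(
                apical_mask, edt, min_diameter_um=config.min_foramen_diameter_mm * 1000.0
            )
        else:
            edt = foramen.DistanceMap(
                np.zeros(apical_mask.data.shape), canal_mask.voxel_size_um
            )
            measurements = []
        main_count = sum(1 for m in measurements if m.kind == "physiological")
        code = axcls.classify_configuration(canal_mask, plan, main_count)
        report.code = str(code)
        report.foramina = [
            {
                "exit_slice": m.exit_slice + apical_recon.origin_index,
                "exit_centroid": list(m.exit_centroid),
                "diameter_um": m.diameter_um,
                "kind": m.kind,
            }
            for m in measurements
        ]
        if config.write_overlay:
            sagittal = foramen.overlay_edt(apical_recon, edt)
            overlay_dir = out_dir / "apical_overlay"
            overlay_dir.mkdir(exist_ok=True)
            for i in range(sagittal.n_slices):
                _write_png(overlay_dir / f"sagittal_{i:04d}.png", sagittal.data[i])
            artifacts["apical_overlay"] = str(overlay_dir)
        if measurements:
            pd.DataFrame(report.foramina).to_csv(out_dir / "foramina.csv", index=False)
            artifacts["foramina_csv"] = str(out_dir / "foramina.csv")
        _report_figure(out_dir / "report.png", profile, plan, windows, counts, code)
        artifacts["report_figure"] = str(out_dir / "report.png")
        timings[stage] = time.perf_counter() - t0

        report.status = "complete"
    except Exception as exc:  # per-tooth failures must not break the batch
        logger.exception("tooth %s failed at stage %s", directory.name, stage)
        report.status = "failed"
        report.failed_stage = stage
        report.error = str(exc)

    report.artifacts = artifacts
    report.timings_s = {k: round(v, 3) for k, v in timings.items()}
    if out_dir.exists():
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
    return report


def _is_tooth_directory(path: Path) -> bool:
    return path.is_dir() and any(
        p.suffix.lower() in volume_io.SLICE_EXTENSIONS for p in path.iterdir()
    )


def batch(root, config: Optional[PipelineConfig] = None, out_root=None) -> pd.DataFrame:
    """Process every tooth directory under ``root``; one report row each.

    Completed directories are served from their cached reports, so re-runs
    after new scans arrive compute only the new teeth.  Per-tooth failures
    are recorded as rows, never raised.  Writes ``cohort.csv``,
    ``cohort.json`` and a preview montage next to the reports.
    """
    root = Path(root)
    config = config or PipelineConfig()
    out_root = Path(out_root) if out_root is not None else root / "analysis"
    out_root.mkdir(parents=True, exist_ok=True)

    tooth_dirs = sorted(
        (
            p
            for p in root.iterdir()
            if p.resolve() != out_root.resolve() and _is_tooth_directory(p)
        ),
        key=lambda p: p.name,
    )
    reports = []
    previews = []
    for tooth_dir in tooth_dirs:
        t0 = time.perf_counter()
        report = process_tooth(tooth_dir, config, out_dir=out_root / tooth_dir.name)
        logger.info(
            "tooth %s: %s in %.1fs", tooth_dir.name, report.status, time.perf_counter() - t0
        )
        reports.append(report)
        mip = out_root / tooth_dir.name / "mip_coronal.png"
        if mip.exists():
            previews.append(iio.imread(mip))

    rows = []
    for r in reports:
        rows.append(
            {
                "tooth_id": r.tooth_id,
                "status": r.status,
                "code": r.code,
                "edb_index": r.edb_index,
                "edb_source": r.edb_source,
                "bottom_index": r.bottom_index,
                "length_mm": r.length_mm,
                "n_foramina": len(r.foramina) if r.foramina is not None else None,
                "failed_stage": r.failed_stage,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "tooth_id", "status", "code", "edb_index", "edb_source",
            "bottom_index", "length_mm", "n_foramina", "failed_stage",
        ],
    )
    table.to_csv(out_root / "cohort.csv", index=False)
    (out_root / "cohort.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=2)
    )
    if previews:
        _write_png(out_root / "batch_overview.png",
                   overview.montage(previews, config.montage_columns))
    return table
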